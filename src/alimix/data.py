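"""Water-chemistry data model, speciation arithmetic, and model-matrix prep.

Cationic ("inorganic", labile) aluminum Al_i is the toxic fraction of
dissolved aluminum in acidified soft waters. It is measured operationally as
the difference between dissolved Al (0.45-um filtrate, Al_d) and organically
complexed Al (cation-exchange eluate, Al_o):

    Al_i = Al_d - Al_o

This module holds the tabular data model (one row per site-date, analytes with
value / censoring-flag / detection-limit triples), the speciation and
threshold-exceedance summaries, the temporal train/test split, correlation
based predictor screening, and standardization into the design structure the
Bayesian model consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "INSITU_FIELDS",
    "PREDICTORS",
    "AnalyteValue",
    "WaterSample",
    "ScalingParams",
    "ModelData",
    "compute_al_i",
    "add_speciation",
    "exceedance_summary",
    "temporal_split",
    "select_predictors",
    "standardize",
    "read_samples_csv",
    "write_samples_csv",
    "samples_to_frame",
]

#: Lab analytes carried as value/censored/detection-limit triples.
#: Metals in ug/L; DOC, SO4, Ca_d, F in mg/L; alkalinity in mg CaCO3/L;
#: color in true color units.
ANALYTES = [
    "Al_d", "Al_o", "DOC", "color", "SO4", "alkalinity", "F",
    "Ca_d", "Ti_d", "Fe_d", "Ce_d", "Li_d",
]

#: In-situ sonde fields (never censored): pH (unitless), water temperature
#: (degC), specific conductance (uS/cm).
INSITU_FIELDS = ["pH_sonde", "temperature", "spc"]

#: Predictor list for the Al_i model, in presentation order.
PREDICTORS = [
    "Al_d", "DOC", "color", "pH_sonde", "temperature", "SO4",
    "alkalinity", "F", "Ca_d", "Ti_d", "Fe_d", "Ce_d", "Li_d",
]

TOXIC_THRESHOLD = 15.0  # ug/L Al_i, assumed harmful to Atlantic salmon


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteValue:
    """One measurement: value, left-censoring status, detection limit.

    ``censored`` means a nondetect: the true value is known only to lie at or
    below ``detection_limit``, and ``value`` is set to the detection limit.
    ``missing`` means no measurement at all; missing and censored are
    mutually exclusive.
    """

    value: float | None
    censored: bool = False
    detection_limit: float | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            if self.censored:
                raise ValueError("a value cannot be both missing and censored")
            if self.value is not None and not (
                isinstance(self.value, float) and math.isnan(self.value)
            ):
                raise ValueError("missing value must have no numeric value")
        elif self.censored:
            if self.detection_limit is None:
                raise ValueError("censored value requires a detection limit")
            if self.value is None or self.value != self.detection_limit:
                raise ValueError(
                    "censored value must equal its detection limit"
                )
        elif self.value is None:
            raise ValueError("non-missing value requires a numeric value")


@dataclass(frozen=True)
class WaterSample:
    """One site-date record: analytes plus in-situ sonde fields."""

    site_id: str
    date: _date
    analytes: Mapping[str, AnalyteValue] = field(default_factory=dict)
    ph_sonde: float | None = None
    temperature: float | None = None
    spc: float | None = None

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")

    @property
    def ordinal_day(self) -> int:
        """Day of year in [1, 366], leap-year aware."""
        return self.date.timetuple().tm_yday


def samples_to_frame(samples: Iterable[WaterSample]) -> pd.DataFrame:
    """Flatten WaterSample records into the wide frame the pipeline uses."""
    rows = []
    for s in samples:
        row: dict = {"site": s.site_id, "date": pd.Timestamp(s.date)}
        row["pH_sonde"] = s.ph_sonde
        row["temperature"] = s.temperature
        row["spc"] = s.spc
        for name, av in s.analytes.items():
            row[name] = np.nan if av.missing else av.value
            row[f"{name}_censored"] = bool(av.censored)
            row[f"{name}_dl"] = (
                np.nan if av.detection_limit is None else av.detection_limit
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
# One row per site-date. Censoring accepted either as a "<DL" text convention
# in the value column (value parsed from the text after "<") or as paired
# <name>_censored / <name>_dl companion columns. Lines starting with "#" are
# provenance headers and are skipped.

def read_samples_csv(path) -> pd.DataFrame:
    """Read the long-format water-chemistry CSV into a wide frame.

    Returns a frame with columns ``site``, ``date`` (datetime64) and, for each
    analyte present, ``<name>`` (float, NaN if missing), ``<name>_censored``
    (bool) and ``<name>_dl`` (float detection limit, NaN if unknown). In-situ
    fields are plain float columns.
    """
    raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=True)
    if "site" not in raw.columns or "date" not in raw.columns:
        raise ValueError("input CSV requires 'site' and 'date' columns")
    out = pd.DataFrame({
        "site": raw["site"].astype(str),
        "date": pd.to_datetime(raw["date"], format="ISO8601"),
    })
    flag_cols = {c for c in raw.columns if c.endswith(("_censored", "_dl"))}
    value_cols = [
        c for c in raw.columns
        if c not in {"site", "date"} and c not in flag_cols
    ]
    for col in value_cols:
        text = raw[col]
        is_lt = text.str.startswith("<", na=False)
        values = pd.to_numeric(text.str.lstrip("<"), errors="coerce")
        censored = is_lt.to_numpy(dtype=bool)
        dl = np.where(censored, values, np.nan)
        if f"{col}_censored" in raw.columns:
            flag = (
                raw[f"{col}_censored"].str.strip().str.lower()
                .isin(["true", "1", "yes", "t"])
            ).to_numpy(dtype=bool)
            censored = censored | flag
        if f"{col}_dl" in raw.columns:
            dl_col = pd.to_numeric(raw[f"{col}_dl"], errors="coerce")
            dl = np.where(np.isfinite(dl_col), dl_col, dl)
        # censored entries report the detection limit as their value
        values = values.to_numpy(dtype=float)
        values = np.where(censored & np.isfinite(dl), dl, values)
        out[col] = values
        if col in ANALYTES:
            out[f"{col}_censored"] = censored
            out[f"{col}_dl"] = dl
        elif censored.any():
            raise ValueError(f"in-situ column {col!r} cannot be censored")
    return out


def write_samples_csv(frame: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write the wide frame using the "<DL" text convention for nondetects."""
    out = pd.DataFrame({
        "site": frame["site"],
        "date": pd.to_datetime(frame["date"]).dt.strftime("%Y-%m-%d"),
    })
    for col in frame.columns:
        if col in ("site", "date") or col.endswith(("_censored", "_dl")):
            continue
        vals = frame[col]
        if f"{col}_censored" in frame.columns:
            cen = frame[f"{col}_censored"].fillna(False).astype(bool)
            text = vals.map(lambda v: "" if pd.isna(v) else format(v, ".6g"))
            text = np.where(cen, "<" + text, text)
            out[col] = text
        else:
            out[col] = vals.map(
                lambda v: "" if pd.isna(v) else format(v, ".6g")
            )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------

def compute_al_i(al_d, al_o, warn_negative: bool = True):
    """Cationic aluminum as the dissolved/organic difference, Al_d - Al_o.

    Accepts scalars or arrays; missing (NaN) inputs propagate to a missing
    result. Negative differences are physically spurious (measurement noise
    in the two determinations) but are returned unchanged, with a warning,
    because deleting them would bias low concentrations upward.
    """
    al_d = np.asarray(al_d, dtype=float)
    al_o = np.asarray(al_o, dtype=float)
    al_i = al_d - al_o
    if warn_negative and np.any(al_i < 0):
        n_neg = int(np.sum(al_i < 0))
        warnings.warn(
            f"{n_neg} negative Al_i value(s) (Al_o > Al_d); retained as-is",
            UserWarning,
            stacklevel=2,
        )
    return al_i if al_i.ndim else float(al_i)


def add_speciation(frame: pd.DataFrame, overwrite: bool = True) -> pd.DataFrame:
    """Append Al_i and %Al_i columns computed from Al_d and Al_o.

    With ``overwrite=False`` an existing Al_i column (a field-speciated
    determination) is kept as-is and only %Al_i is derived. When computing
    Al_i, rows where Al_d or Al_o is censored or missing get missing Al_i
    (the subtraction is undefined below a detection limit). %Al_i = Al_i /
    Al_d is missing wherever Al_d <= 0, censored, or missing.
    """
    out = frame.copy()
    al_d = out["Al_d"].to_numpy(dtype=float)
    al_d_cen = (
        out["Al_d_censored"].fillna(False).to_numpy(dtype=bool)
        if "Al_d_censored" in out.columns
        else np.zeros(len(out), dtype=bool)
    )
    if overwrite or "Al_i" not in out.columns:
        al_o = out["Al_o"].to_numpy(dtype=float)
        bad = al_d_cen | ~np.isfinite(al_d) | ~np.isfinite(al_o)
        if "Al_o_censored" in out.columns:
            bad |= out["Al_o_censored"].fillna(False).to_numpy(dtype=bool)
        al_i = np.asarray(compute_al_i(al_d, al_o, warn_negative=False))
        al_i = np.where(bad, np.nan, al_i)
        n_neg = int(np.nansum(al_i < 0))
        if n_neg:
            warnings.warn(
                f"{n_neg} negative Al_i value(s) (Al_o > Al_d); retained as-is",
                UserWarning,
                stacklevel=2,
            )
        out["Al_i"] = al_i
    else:
        al_i = out["Al_i"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where((al_d > 0) & ~al_d_cen, al_i / al_d, np.nan)
    out["pct_Al_i"] = pct
    return out


def exceedance_summary(
    frame: pd.DataFrame,
    threshold: float = TOXIC_THRESHOLD,
    value_col: str = "Al_i",
) -> tuple[pd.DataFrame, dict]:
    """Per-site and global exceedance of a toxicity threshold.

    ``ever_exceeded`` means at least one observation strictly above the
    threshold; ``median_exceeded`` compares the per-site median of non-missing
    values. Sites with no non-missing values are excluded from the global
    counts and reported separately.
    """
    per_site = []
    excluded = []
    for site, grp in frame.groupby("site", sort=True):
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            excluded.append(site)
            continue
        med = float(np.median(vals))
        per_site.append({
            "site": site,
            "n": int(vals.size),
            "n_exceed": int(np.sum(vals > threshold)),
            "median_al_i": med,
            "ever_exceeded": bool(np.any(vals > threshold)),
            "median_exceeded": bool(med > threshold),
        })
    table = pd.DataFrame(
        per_site,
        columns=[
            "site", "n", "n_exceed", "median_al_i",
            "ever_exceeded", "median_exceeded",
        ],
    )
    overall = {
        "threshold": float(threshold),
        "n_sites": int(len(table)),
        "n_sites_ever_exceeded": int(table["ever_exceeded"].sum()) if len(table) else 0,
        "n_sites_median_exceeded": int(table["median_exceeded"].sum()) if len(table) else 0,
        "sites_excluded": excluded,
    }
    return table, overall


# ---------------------------------------------------------------------------
# Temporal split
# ---------------------------------------------------------------------------

def temporal_split(
    frame: pd.DataFrame,
    test_fraction: float = 0.2,
    min_obs: int = 5,
) -> pd.Series:
    """Label the most recent ceil(test_fraction * n) rows per site as test.

    Sites with fewer than ``min_obs`` observations contribute all rows to the
    training set. Within-site date ties are broken by stable input order, so
    the earliest-entered of two same-day samples stays in training.
    """
    labels = pd.Series("train", index=frame.index, name="split")
    dates = pd.to_datetime(frame["date"])
    for _, grp in frame.groupby("site", sort=False):
        n = len(grp)
        if n < min_obs:
            continue
        n_test = math.ceil(test_fraction * n)
        order = dates.loc[grp.index].argsort(kind="stable")
        test_pos = order.iloc[-n_test:] if n_test > 0 else order.iloc[:0]
        labels.loc[grp.index[test_pos]] = "test"
    return labels


# ---------------------------------------------------------------------------
# Predictor screening
# ---------------------------------------------------------------------------

def _unobserved_fraction(frame: pd.DataFrame, name: str) -> float:
    missing = frame[name].isna()
    cen_col = f"{name}_censored"
    censored = (
        frame[cen_col].fillna(False).astype(bool)
        if cen_col in frame.columns
        else pd.Series(False, index=frame.index)
    )
    return float((missing | censored).mean())


def select_predictors(
    train: pd.DataFrame,
    response: str = "Al_i",
    candidates: Sequence[str] | None = None,
    r_min: float = 0.1,
    max_unobserved: float = 0.5,
    supplementary: Sequence[str] = (),
) -> tuple[list[str], pd.DataFrame]:
    """Screen candidate predictors for the Al_i model.

    A candidate is kept when its pairwise-complete Pearson correlation with
    the response exceeds ``r_min`` in absolute value, or when it belongs to
    ``supplementary`` (variables required by the missing-value sub-model
    system regardless of marginal correlation). Candidates that are more than
    ``max_unobserved`` missing-or-censored are dropped unconditionally.
    Censored values enter the screening correlation at their detection limit
    (a pre-model heuristic only; the model itself treats them as bounded
    parameters). Returns the kept list (input order) and a screening report.
    """
    if candidates is None:
        candidates = [c for c in PREDICTORS if c in train.columns]
    if len(train) == 0:
        raise ValueError("training set is empty")
    supplementary = set(supplementary)
    y = train[response].to_numpy(dtype=float)
    rows, kept = [], []
    for name in candidates:
        x = train[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        frac_unobs = _unobserved_fraction(train, name)
        r = np.nan
        reason = ""
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        elif name not in supplementary:
            warnings.warn(
                f"correlation with {response} undefined for {name!r}; excluded",
                UserWarning,
                stacklevel=2,
            )
        if frac_unobs > max_unobserved:
            reason = f">{max_unobserved:.0%} missing or censored"
            selected = False
        elif name in supplementary:
            reason = "supplementary (sub-model system)"
            selected = True
        elif np.isfinite(r) and abs(r) > r_min:
            reason = f"|r| > {r_min}"
            selected = True
        else:
            reason = f"|r| <= {r_min}" if np.isfinite(r) else "r undefined"
            selected = False
        if selected:
            kept.append(name)
        rows.append({
            "variable": name,
            "r": r,
            "frac_unobserved": frac_unobs,
            "selected": selected,
            "reason": reason,
        })
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardization and the model design structure
# ---------------------------------------------------------------------------

@dataclass
class ScalingParams:
    """Per-variable affine transform (x - location) / scale.

    Locations and scales are estimated from observed (non-missing,
    non-censored) training entries only, with the n-1 denominator for the
    standard deviation, and applied identically to training and test rows.
    """

    location: dict[str, float]
    scale: dict[str, float]

    def transform(self, name: str, values):
        return (np.asarray(values, dtype=float) - self.location[name]) / self.scale[name]

    def inverse(self, name: str, values):
        return np.asarray(values, dtype=float) * self.scale[name] + self.location[name]


@dataclass
class ModelData:
    """Standardized design structure for the Bayesian mixed model.

    Exactly one of observed / missing / censored holds per predictor cell:
    observed cells carry their standardized value in ``X``; missing cells are
    NaN in ``X``; censored cells carry the standardized detection limit in
    both ``X`` and ``censor_bounds``.
    """

    y: np.ndarray                  # (n,) standardized response
    X: np.ndarray                  # (n, p)
    predictors: list[str]
    missing_mask: np.ndarray       # (n, p) bool
    censored_mask: np.ndarray      # (n, p) bool
    censor_bounds: np.ndarray      # (n, p), +inf where not censored
    site_index: np.ndarray         # (n,) int codes in [0, J)
    site_labels: list[str]
    ordinal_day: np.ndarray        # (n,) int day-of-year
    split_label: np.ndarray        # (n,) "train" / "test"

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def validate(self) -> None:
        if np.any(self.missing_mask & self.censored_mask):
            raise ValueError("cells cannot be both missing and censored")
        observed = ~(self.missing_mask | self.censored_mask)
        if not np.all(np.isfinite(self.X[observed])):
            raise ValueError("observed cells must be finite")
        if not np.all(np.isfinite(self.censor_bounds[self.censored_mask])):
            raise ValueError("censored cells require finite bounds")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response must be fully observed")

    def subset(self, rows: np.ndarray) -> "ModelData":
        return ModelData(
            y=self.y[rows],
            X=self.X[rows],
            predictors=list(self.predictors),
            missing_mask=self.missing_mask[rows],
            censored_mask=self.censored_mask[rows],
            censor_bounds=self.censor_bounds[rows],
            site_index=self.site_index[rows],
            site_labels=list(self.site_labels),
            ordinal_day=self.ordinal_day[rows],
            split_label=self.split_label[rows],
        )

    def train(self) -> "ModelData":
        return self.subset(self.split_label == "train")

    def test(self) -> "ModelData":
        return self.subset(self.split_label == "test")


def standardize(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    split_label: pd.Series | None = None,
    response: str = "Al_i",
) -> tuple[ModelData, ScalingParams]:
    """Standardize response and predictors and assemble a ModelData.

    Rows with a missing response are dropped (with a warning) — the model
    requires an observed Al_i per likelihood row. Scaling locations and
    scales come from observed training entries only; censored detection
    limits are mapped through the same affine transform.
    """
    if split_label is None:
        split_label = pd.Series("train", index=frame.index)
    keep = frame[response].notna()
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(
            f"dropping {n_drop} row(s) with missing {response}",
            UserWarning,
            stacklevel=2,
        )
    frame = frame.loc[keep]
    split = split_label.loc[frame.index].to_numpy(dtype=object).astype(str)
    is_train = split == "train"

    location, scale = {}, {}
    for name in [response, *predictors]:
        vals = frame[name].to_numpy(dtype=float)
        cen_col = f"{name}_censored"
        censored = (
            frame[cen_col].fillna(False).to_numpy(dtype=bool)
            if cen_col in frame.columns
            else np.zeros(len(frame), dtype=bool)
        )
        obs = np.isfinite(vals) & ~censored & is_train
        if obs.sum() < 2:
            raise ValueError(f"variable {name!r} has <2 observed training values")
        loc = float(np.mean(vals[obs]))
        sd = float(np.std(vals[obs], ddof=1))
        if sd <= 0:
            raise ValueError(f"variable {name!r} has zero scale in training set")
        location[name], scale[name] = loc, sd

    scaling = ScalingParams(location=location, scale=scale)

    n, p = len(frame), len(predictors)
    X = np.full((n, p), np.nan)
    missing = np.zeros((n, p), dtype=bool)
    censored = np.zeros((n, p), dtype=bool)
    bounds = np.full((n, p), np.inf)
    for j, name in enumerate(predictors):
        vals = frame[name].to_numpy(dtype=float)
        cen_col = f"{name}_censored"
        cen = (
            frame[cen_col].fillna(False).to_numpy(dtype=bool)
            if cen_col in frame.columns
            else np.zeros(n, dtype=bool)
        )
        std = scaling.transform(name, vals)
        X[:, j] = std
        missing[:, j] = ~np.isfinite(vals)
        censored[:, j] = cen & np.isfinite(vals)
        bounds[censored[:, j], j] = std[censored[:, j]]

    sites = frame["site"].astype(str)
    site_labels = sorted(sites.unique())
    site_code = {s: i for i, s in enumerate(site_labels)}
    dates = pd.to_datetime(frame["date"])

    data = ModelData(
        y=scaling.transform(response, frame[response].to_numpy(dtype=float)),
        X=X,
        predictors=list(predictors),
        missing_mask=missing,
        censored_mask=censored,
        censor_bounds=bounds,
        site_index=sites.map(site_code).to_numpy(dtype=int),
        site_labels=site_labels,
        ordinal_day=dates.dt.dayofyear.to_numpy(dtype=int),
        split_label=split,
    )
    data.validate()
    return data, scaling
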