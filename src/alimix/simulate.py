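"""Synthetic water-chemistry generator with known truth.

Generates site-date records whose dependence structure matches the
assumptions of the Al_i model: a directed acyclic chain of predictor
sub-models (DOC driving Al_d, color and Fe_d; Al_d driving Ti_d and pH;
Ca_d driving SO4 and alkalinity; F driving Li_d; Fe_d driving Ce_d; a
seasonal cycle driving water temperature), per-site random intercepts,
t-distributed residuals, completely-at-random missingness, and
left-censoring at known detection limits.

Variables are generated on a standardized latent scale following the DAG and
then mapped affinely to realistic original units (soft-water ranges: DOC
around 9-18 mg/L, Al_d around 200-420 ug/L, pH 4.2-4.7, Ca_d 0.7-1.6 mg/L).
The emitted Al_i column plays the role of the field-speciated determination:
it is internally consistent with Al_d - Al_o on the true (uncensored) scale,
and lab-side nondetects in Al_d therefore do not remove the response.

The default coefficient vector is the set of standardized effect sizes the
package's model is designed around (dissolved Al dominant and positive, DOC
negative after conditioning, dissolved Ti/Fe positive, F negative), with
sub-model slopes tuned so the *marginal* correlation of DOC with Al_i stays
positive while its partial coefficient is negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .data import ANALYTES, PREDICTORS

__all__ = ["SubmodelTruth", "SyntheticTruth", "generate", "truth_report", "load_truth"]

STUDY_START = "2015-01-01"
STUDY_END = "2022-12-31"
PERIOD = 365.25


@dataclass(frozen=True)
class SubmodelTruth:
    """One predictor's generating equation on the standardized scale."""

    kind: str                    # "intercept" | "slope" | "seasonal"
    parent: str | None
    coef: float                  # slope (slope kind) or intercept level
    sigma: float                 # residual scale
    nu: float                    # residual t degrees of freedom


def _default_submodels() -> dict[str, SubmodelTruth]:
    s = SubmodelTruth
    return {
        "DOC": s("intercept", None, 0.0, 1.0, 30.0),
        "Ca_d": s("intercept", None, 0.0, 1.0, 30.0),
        "F": s("intercept", None, 0.0, 1.0, 30.0),
        "Al_d": s("slope", "DOC", 0.65, 0.76, 30.0),
        "Ti_d": s("slope", "Al_d", 0.70, 0.71, 30.0),
        "color": s("slope", "DOC", 0.80, 0.60, 30.0),
        "Fe_d": s("slope", "DOC", 0.75, 0.66, 30.0),
        "Ce_d": s("slope", "Fe_d", 0.80, 0.60, 30.0),
        "pH_sonde": s("slope", "Al_d", -0.60, 0.80, 30.0),
        "SO4": s("slope", "Ca_d", 0.60, 0.80, 30.0),
        "alkalinity": s("slope", "Ca_d", 0.70, 0.71, 30.0),
        "Li_d": s("slope", "F", 0.60, 0.80, 30.0),
        "temperature": s("seasonal", None, 0.0, 0.50, 30.0),
    }


#: Standardized fixed-effect coefficients, in PREDICTORS order.
DEFAULT_BETA = {
    "Al_d": 0.79, "DOC": -0.33, "color": -0.01, "pH_sonde": 0.08,
    "temperature": 0.10, "SO4": 0.04, "alkalinity": -0.06, "F": -0.11,
    "Ca_d": 0.03, "Ti_d": 0.20, "Fe_d": 0.16, "Ce_d": -0.07, "Li_d": 0.05,
}

#: Original-unit (location, scale) per variable; soft-water ranges.
DEFAULT_SCALING = {
    "Al_i": (30.0, 22.0),       # ug/L
    "Al_d": (300.0, 110.0),     # ug/L
    "DOC": (13.0, 5.5),         # mg/L
    "color": (60.0, 25.0),      # TCU
    "SO4": (2.3, 0.8),          # mg/L
    "alkalinity": (0.8, 0.9),   # mg CaCO3/L (can be negative in acid water)
    "F": (0.03, 0.012),         # mg/L
    "Ca_d": (1.1, 0.35),        # mg/L
    "Ti_d": (1.5, 0.7),         # ug/L
    "Fe_d": (250.0, 120.0),     # ug/L
    "Ce_d": (0.15, 0.08),       # ug/L
    "Li_d": (0.5, 0.2),         # ug/L
    "pH_sonde": (4.6, 0.5),
    "temperature": (10.0, 6.0),  # degC
    "spc": (38.0, 10.0),        # uS/cm
}

#: Lab-measured variables eligible for left-censoring by default.
DEFAULT_CENSOR_VARS = ["Al_d", "F", "Ti_d", "Fe_d", "Ce_d", "Li_d", "SO4"]


@dataclass
class SyntheticTruth:
    """Full generating configuration plus everything recorded at generation.

    ``site_effects``, ``detection_limits`` and ``complete_data`` are filled
    in by :func:`generate`; ``complete_data`` (the pre-missingness,
    pre-censoring frame) is carried in memory for recovery tests but is not
    serialized by :func:`truth_report`.
    """

    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma: float = 0.4
    nu: float = 15.0
    sigma_alpha: float = 0.5
    submodels: dict[str, SubmodelTruth] = field(default_factory=_default_submodels)
    temp_amplitude: float = 1.1
    temp_phase: float = 200.0            # day of annual temperature peak
    scaling: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALING)
    )
    missing_rate: float | Mapping[str, float] = 0.08
    censor_rate: float | Mapping[str, float] = 0.08
    censor_vars: list[str] = field(default_factory=lambda: list(DEFAULT_CENSOR_VARS))
    seasonal_missing: bool = False
    seed: int | None = None
    site_effects: np.ndarray | None = None
    detection_limits: dict[str, float] | None = None
    complete_data: pd.DataFrame | None = field(default=None, repr=False)

    def rate(self, which: str, name: str) -> float:
        raw = self.missing_rate if which == "missing" else self.censor_rate
        r = raw.get(name, 0.0) if isinstance(raw, Mapping) else float(raw)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{which} rate for {name!r} outside [0, 1]: {r}")
        return r


def _topological_order(submodels: Mapping[str, SubmodelTruth]) -> list[str]:
    order: list[str] = []
    seen: set[str] = set()

    def visit(name: str, stack: tuple[str, ...]) -> None:
        if name in seen:
            return
        if name in stack:
            raise ValueError(f"cyclic sub-model dependency at {name!r}")
        sm = submodels[name]
        if sm.parent is not None:
            visit(sm.parent, stack + (name,))
        seen.add(name)
        order.append(name)

    for name in submodels:
        visit(name, ())
    return order


def generate(
    n_sites: int = 10,
    n_per_site: int = 40,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic dataset and return (samples, completed truth).

    Generation follows the sub-model DAG (parent variables first), then the
    response from the site intercepts, the linear predictor and t noise, then
    MCAR missingness per variable, then left-censoring: non-missing values
    below a variable's detection limit are replaced by the limit and flagged.
    """
    if n_sites < 2 or n_per_site < 3:
        raise ValueError("need at least 2 sites and 3 observations per site")
    truth = truth if truth is not None else SyntheticTruth()
    rng = np.random.default_rng(seed)
    n = n_sites * n_per_site

    site_labels = [f"S{i + 1:03d}" for i in range(n_sites)]
    site_idx = np.repeat(np.arange(n_sites), n_per_site)
    start = pd.Timestamp(STUDY_START)
    span_days = (pd.Timestamp(STUDY_END) - start).days
    dates = start + pd.to_timedelta(
        np.sort(
            rng.integers(0, span_days + 1, size=(n_sites, n_per_site)), axis=1
        ).ravel(),
        unit="D",
    )
    t_day = dates.dayofyear.to_numpy(dtype=float)

    # latent standardized variables, DAG order
    z: dict[str, np.ndarray] = {}
    for name in _topological_order(truth.submodels):
        sm = truth.submodels[name]
        noise = sm.sigma * rng.standard_t(sm.nu, size=n)
        if sm.kind == "intercept":
            z[name] = sm.coef + noise
        elif sm.kind == "slope":
            z[name] = sm.coef * z[sm.parent] + noise
        elif sm.kind == "seasonal":
            seasonal = truth.temp_amplitude * np.cos(
                2 * np.pi * (t_day - truth.temp_phase) / PERIOD
            )
            z[name] = sm.coef + seasonal + noise
        else:
            raise ValueError(f"unknown sub-model kind {sm.kind!r}")

    site_effects = (
        truth.site_effects
        if truth.site_effects is not None
        else rng.normal(0.0, truth.sigma_alpha, size=n_sites)
    )
    mu = site_effects[site_idx] + sum(
        truth.beta[name] * z[name] for name in truth.beta
    )
    y = mu + truth.sigma * rng.standard_t(truth.nu, size=n)

    # map to original units
    frame = pd.DataFrame({"site": np.array(site_labels)[site_idx], "date": dates})
    loc_y, scale_y = truth.scaling["Al_i"]
    frame["Al_i"] = loc_y + scale_y * y
    for name in z:
        loc, scale = truth.scaling[name]
        frame[name] = loc + scale * z[name]
    frame["Al_o"] = frame["Al_d"] - frame["Al_i"]
    loc_spc, scale_spc = truth.scaling["spc"]
    frame["spc"] = loc_spc + scale_spc * rng.standard_normal(n)
    complete = frame.copy()

    # missingness (MCAR per variable; optional winter-weighted variant)
    winter = np.isin(dates.month.to_numpy(), [12, 1, 2, 3])
    for name in PREDICTORS:
        r = truth.rate("missing", name)
        if r <= 0:
            continue
        prob = np.full(n, r)
        if truth.seasonal_missing:
            prob = np.where(winter, np.minimum(1.0, 2.0 * r), r)
            prob *= r * n / max(prob.sum(), 1e-12)  # keep the overall rate
        drop = rng.random(n) < prob
        frame.loc[drop, name] = np.nan

    # left-censoring at known limits
    limits = dict(truth.detection_limits or {})
    for name in ANALYTES:
        if f"{name}_censored" not in frame.columns:
            frame[f"{name}_censored"] = False
        if f"{name}_dl" not in frame.columns:
            frame[f"{name}_dl"] = np.nan
    censorable = [v for v in truth.censor_vars if truth.rate("censor", v) > 0]
    for name in censorable:
        if name not in limits:
            loc, scale = truth.scaling[name]
            limits[name] = float(loc + scale * norm.ppf(truth.rate("censor", name)))
        lim = limits[name]
        vals = frame[name].to_numpy(dtype=float)
        cen = np.isfinite(vals) & (vals < lim)
        frame.loc[cen, name] = lim
        frame[f"{name}_censored"] = cen
        frame[f"{name}_dl"] = lim

    out_truth = SyntheticTruth(
        beta=dict(truth.beta),
        sigma=truth.sigma,
        nu=truth.nu,
        sigma_alpha=truth.sigma_alpha,
        submodels=dict(truth.submodels),
        temp_amplitude=truth.temp_amplitude,
        temp_phase=truth.temp_phase,
        scaling=dict(truth.scaling),
        missing_rate=truth.missing_rate,
        censor_rate=truth.censor_rate,
        censor_vars=list(truth.censor_vars),
        seasonal_missing=truth.seasonal_missing,
        seed=seed,
        site_effects=np.asarray(site_effects, dtype=float),
        detection_limits=limits,
        complete_data=complete,
    )
    return frame, out_truth


def standardized_true_beta(truth: SyntheticTruth, scaling) -> dict[str, float]:
    """True fixed effects on the fitted model's standardized scale.

    The generator works on a latent scale and maps each variable affinely to
    original units; the model standardizes with empirical training moments.
    Both maps are affine, so the true coefficient seen by the model is

        beta_j * (gen_scale_y / gen_scale_xj) * (fit_scale_xj / fit_scale_y)

    where gen_* are the generator's unit scales and fit_* the empirical
    standardization scales actually applied (a ScalingParams).
    """
    gen_y = truth.scaling["Al_i"][1]
    fit_y = scaling.scale["Al_i"]
    return {
        name: b * (gen_y / truth.scaling[name][1]) * (scaling.scale[name] / fit_y)
        for name, b in truth.beta.items()
    }


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def truth_report(truth: SyntheticTruth, path=None) -> str:
    """Serialize the generating parameters to YAML (human- and machine-readable)."""
    doc = {
        "beta": {k: float(v) for k, v in truth.beta.items()},
        "sigma": float(truth.sigma),
        "nu": float(truth.nu),
        "sigma_alpha": float(truth.sigma_alpha),
        "submodels": {
            k: {
                "kind": sm.kind,
                "parent": sm.parent,
                "coef": float(sm.coef),
                "sigma": float(sm.sigma),
                "nu": float(sm.nu),
            }
            for k, sm in truth.submodels.items()
        },
        "temp_amplitude": float(truth.temp_amplitude),
        "temp_phase": float(truth.temp_phase),
        "scaling": {k: [float(a), float(b)] for k, (a, b) in truth.scaling.items()},
        "missing_rate": (
            dict(truth.missing_rate)
            if isinstance(truth.missing_rate, Mapping)
            else float(truth.missing_rate)
        ),
        "censor_rate": (
            dict(truth.censor_rate)
            if isinstance(truth.censor_rate, Mapping)
            else float(truth.censor_rate)
        ),
        "censor_vars": list(truth.censor_vars),
        "seasonal_missing": bool(truth.seasonal_missing),
        "seed": truth.seed,
        "site_effects": (
            None
            if truth.site_effects is None
            else [float(v) for v in truth.site_effects]
        ),
        "detection_limits": (
            None
            if truth.detection_limits is None
            else {k: float(v) for k, v in truth.detection_limits.items()}
        ),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def load_truth(source) -> SyntheticTruth:
    """Inverse of :func:`truth_report` (complete_data is not round-tripped)."""
    if isinstance(source, str) and "\n" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, io.IOBase):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(source)
    submodels = {
        k: SubmodelTruth(**v) for k, v in doc["submodels"].items()
    }
    return SyntheticTruth(
        beta=doc["beta"],
        sigma=doc["sigma"],
        nu=doc["nu"],
        sigma_alpha=doc["sigma_alpha"],
        submodels=submodels,
        temp_amplitude=doc["temp_amplitude"],
        temp_phase=doc["temp_phase"],
        scaling={k: (v[0], v[1]) for k, v in doc["scaling"].items()},
        missing_rate=doc["missing_rate"],
        censor_rate=doc["censor_rate"],
        censor_vars=doc["censor_vars"],
        seasonal_missing=doc["seasonal_missing"],
        seed=doc["seed"],
        site_effects=(
            None if doc["site_effects"] is None else np.asarray(doc["site_effects"])
        ),
        detection_limits=doc["detection_limits"],
    )
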