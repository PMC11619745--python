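"""Validation studies: oracle comparisons, calibration, parameter recovery.

These routines exercise the package end to end under controlled synthetic
conditions with known truth. They are used by the acceptance script and the
test suite; each returns plain dictionaries of measured quantities and never
hard-codes an expected value.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .blmm import ModelSpec, build_model, fit
from .data import PREDICTORS, exceedance_summary, select_predictors, standardize, temporal_split
from .evaluate import mae_with_interval, posterior_predict, t_median_absolute_error
from .simulate import SyntheticTruth, generate, standardized_true_beta
from .splines import build_spline_basis, cyclic_spline_matrix
from .trends import mann_kendall

__all__ = [
    "mk_bruteforce_agreement",
    "mk_type1_error",
    "recovery_study",
    "gaussian_limit_study",
    "predictive_noise_floor",
    "selection_and_split_study",
    "spline_checks",
    "headline_pipeline",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


# ---------------------------------------------------------------------------
# Trend statistics vs brute force
# ---------------------------------------------------------------------------

def mk_bruteforce_agreement(n_vectors: int = 500, max_n: int = 50, seed: int = 0) -> dict:
    """Fraction of random (tied) vectors where S and tau match an O(n^2) oracle."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_vectors):
        n = int(rng.integers(3, max_n + 1))
        if rng.random() < 0.5:
            x = rng.integers(0, max(2, n // 3), size=n).astype(float)  # heavy ties
        else:
            x = np.round(rng.normal(size=n), 1)
        if len(np.unique(x)) < 2:
            x[0] += 1.0
        # oracle: explicit pair loops and tie-corrected denominator
        s = sum(
            np.sign(x[j] - x[i])
            for i in range(n)
            for j in range(i + 1, n)
        )
        _, counts = np.unique(x, return_counts=True)
        t = counts[counts > 1]
        d0 = n * (n - 1) / 2
        denom = math.sqrt((d0 - np.sum(t * (t - 1) / 2)) * d0)
        res = mann_kendall(x)
        matches += res.S == int(s) and abs(res.tau - s / denom) < 1e-12
    return {"agreement": matches / n_vectors, "n": n_vectors}


def mk_type1_error(
    n: int = 20, replicates: int = 2000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical rejection rate of the trend test under an iid Gaussian null."""
    rng = np.random.default_rng(seed)
    rejections = sum(
        mann_kendall(rng.normal(size=n)).p_value < alpha for _ in range(replicates)
    )
    return {"type1_error": rejections / replicates, "n": replicates}


# ---------------------------------------------------------------------------
# Parameter recovery with missingness and censoring
# ---------------------------------------------------------------------------

def recovery_study(
    n_replicates: int = 20,
    n_sites: int = 10,
    n_per_site: int = 40,
    missing_rate: float = 0.1,
    censor_rate: float = 0.1,
    chains: int = 2,
    draws: int = 500,
    warmup: int = 500,
    seed: int = 0,
) -> dict:
    """Credible-interval coverage of the fixed effects over synthetic replicates.

    Every replicate draws fresh sites, dates, missingness and nondetects
    (censoring applied to all predictors), fits the full joint model, and
    checks whether each 95% interval covers the true standardized
    coefficient. Censored-cell draws are simultaneously audited against
    their bounds.
    """
    seeds = _child_seeds(seed, 2 * n_replicates)
    coverage = {name: 0 for name in PREDICTORS}
    violations = 0
    n_censored_draws = 0
    for k in range(n_replicates):
        truth_in = SyntheticTruth(
            missing_rate=missing_rate,
            censor_rate=censor_rate,
            censor_vars=list(PREDICTORS),
        )
        frame, truth = generate(n_sites, n_per_site, truth_in, seed=seeds[2 * k])
        data, scaling = standardize(frame, PREDICTORS)
        model = build_model(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fit(
                model,
                chains=chains,
                draws_per_chain=draws,
                warmup=warmup,
                seed=seeds[2 * k + 1],
            )
        target = standardized_true_beta(truth, scaling)
        beta = result.stacked("beta")
        for j, name in enumerate(result.predictors):
            lo, hi = np.quantile(beta[:, j], [0.025, 0.975])
            coverage[name] += int(lo <= target[name] <= hi)
        violations += result.censoring_violations()
        n_censored_draws += int(result.cell_censored.sum()) * beta.shape[0]
    return {
        "coverage": coverage,
        "min_coverage": min(coverage.values()),
        "mean_coverage": float(np.mean(list(coverage.values()))),
        "n_replicates": n_replicates,
        "censoring_violations": violations,
        "n_censored_draws": n_censored_draws,
    }


# ---------------------------------------------------------------------------
# Gaussian limit vs penalized least squares
# ---------------------------------------------------------------------------

def gaussian_limit_study(seed: int = 0, chains: int = 2, draws: int = 400) -> dict:
    """Fix nu = 1000 on complete data; compare posterior medians with ridge.

    The reference is the penalized least-squares solution using the fitted
    scales: an unpenalized global intercept, site effects penalized by
    sigma^2/sigma_alpha^2, and coefficients penalized by sigma^2/tau^2.
    Reported is the largest |median - ridge| in units of the posterior sd.
    """
    s1, s2 = _child_seeds(seed, 2)
    truth_in = SyntheticTruth(missing_rate=0.0, censor_rate=0.0)
    truth_in.nu = 1000.0
    frame, _ = generate(8, 40, truth_in, seed=s1)
    data, _ = standardize(frame, PREDICTORS)
    spec = ModelSpec(predictors=list(data.predictors), nu_fixed=1000.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fit(
            build_model(data, spec), chains=chains, draws_per_chain=draws,
            warmup=draws, seed=s2,
        )
    beta = result.stacked("beta")
    med, sd = np.median(beta, axis=0), np.std(beta, axis=0)
    sigma2 = float(np.median(result.stacked("sigma")) ** 2)
    tau2 = float(np.median(result.stacked("tau")) ** 2)
    sa2 = float(np.median(result.stacked("sigma_alpha")) ** 2)
    X, y, site = data.X, data.y, data.site_index
    n, p = X.shape
    J = data.n_sites
    Z = np.zeros((n, J))
    Z[np.arange(n), site] = 1.0
    D = np.column_stack([np.ones(n), Z, X])
    penalty = np.concatenate(
        [[1e-8], np.full(J, sigma2 / sa2), np.full(p, sigma2 / tau2)]
    )
    coef = np.linalg.solve(D.T @ D + np.diag(penalty), D.T @ y)
    max_z = float(np.max(np.abs(med - coef[1 + J:]) / sd))
    return {"max_z": max_z, "n": n}


# ---------------------------------------------------------------------------
# Predictive noise floor
# ---------------------------------------------------------------------------

def predictive_noise_floor(seed: int = 0, chains: int = 2, draws: int = 400) -> dict:
    """Test-set predictive MAE against the closed-form noise floor.

    On complete data the irreducible median absolute error is the median of
    |sigma * t_nu| mapped to ug/L; a well-fit model's posterior-predictive
    MAE should sit at that floor (up to estimation noise).
    """
    s1, s2, s3 = _child_seeds(seed, 3)
    truth_in = SyntheticTruth(missing_rate=0.0, censor_rate=0.0)
    frame, truth = generate(12, 50, truth_in, seed=s1)
    split = temporal_split(frame)
    data, scaling = standardize(frame, PREDICTORS, split)
    train = data.train()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fit(
            build_model(train), chains=chains, draws_per_chain=draws,
            warmup=draws, seed=s2,
        )
    test = data.test()
    pred = posterior_predict(result, test, scaling, seed=s3)
    observed = scaling.inverse("Al_i", test.y)
    mae = mae_with_interval(pred, observed)
    theory = t_median_absolute_error(
        truth.sigma, truth.nu, scale=truth.scaling["Al_i"][1]
    )
    return {
        "mae": mae["Q50"],
        "theory": theory,
        "ratio": mae["Q50"] / theory,
        "n_test": mae["n"],
    }


# ---------------------------------------------------------------------------
# Split and selection rules
# ---------------------------------------------------------------------------

def selection_and_split_study(seed: int = 0) -> dict:
    """Check the temporal split and screening rules on rule-satisfying data.

    Generates a large dataset whose marginal correlations respect the
    screening thresholds, then verifies that (1) the per-site split takes the
    ceil(20%) most recent rows of every site with >= 5 observations, (2) the
    |r| > 0.1-or-supplementary rule minus the >50%-unobserved rule returns
    exactly the model predictor list, (3) a pure-noise candidate (specific
    conductance) is excluded, and (4) a mostly-missing variable is excluded.
    """
    truth_in = SyntheticTruth(missing_rate=0.05, censor_rate=0.05)
    frame, _ = generate(20, 100, truth_in, seed=_child_seeds(seed, 1)[0])
    split = temporal_split(frame, 0.2, 5)
    split_ok = True
    for _, grp in frame.groupby("site"):
        n = len(grp)
        n_test = int((split.loc[grp.index] == "test").sum())
        expected = math.ceil(0.2 * n) if n >= 5 else 0
        split_ok &= n_test == expected
        if n_test:
            dates = grp["date"]
            sub = split.loc[grp.index]
            split_ok &= dates[sub == "train"].max() <= dates[sub == "test"].min()

    train = frame[(split == "train") & frame["Al_i"].notna()].copy()
    # a variable that fails the >50% missing-or-censored rule
    rng = np.random.default_rng(seed)
    doomed = train["Al_d"] * 0.5
    doomed[rng.random(len(train)) < 0.6] = np.nan
    train["mostly_missing"] = doomed
    selected, report = select_predictors(
        train,
        candidates=[*PREDICTORS, "spc", "mostly_missing"],
        r_min=0.1,
        max_unobserved=0.5,
        supplementary=[
            "temperature", "SO4", "alkalinity", "F", "Ca_d", "Li_d",
        ],
    )
    list_match = selected == list(PREDICTORS)
    spc_row = report.set_index("variable").loc["spc"]
    missing_row = report.set_index("variable").loc["mostly_missing"]
    return {
        "split_ok": bool(split_ok),
        "list_match": bool(list_match),
        "selected": selected,
        "spc_excluded": bool(not spc_row["selected"]),
        "mostly_missing_excluded": bool(not missing_row["selected"]),
        "n_train": len(train),
    }


# ---------------------------------------------------------------------------
# Spline checks
# ---------------------------------------------------------------------------

def spline_checks(n_basis: int = 8) -> dict:
    """Period-boundary cyclicity and sine recovery of the seasonal basis."""
    basis = build_spline_basis(np.arange(1, 367), n_basis=n_basis)
    gap = float(np.max(np.abs(basis.evaluate([0.0]) - basis.evaluate([basis.period]))))
    t = np.linspace(0.0, 365.25, 100, endpoint=False)
    target = np.sin(2 * np.pi * t / 365.25)
    fit_basis = build_spline_basis(t, n_basis=n_basis)
    coef, *_ = np.linalg.lstsq(fit_basis.Z, target, rcond=None)
    dense = np.linspace(0, 365.25, 1000)
    fitted = cyclic_spline_matrix(dense, fit_basis.knots, fit_basis.period) @ coef
    err = float(np.max(np.abs(fitted - np.sin(2 * np.pi * dense / 365.25))))
    return {"boundary_gap": gap, "sine_max_error": err, "n_basis": n_basis}


# ---------------------------------------------------------------------------
# Headline synthetic pipeline quantities
# ---------------------------------------------------------------------------

def headline_pipeline(seed: int = 0, chains: int = 2, draws: int = 400) -> dict:
    """Exceedance status and train/test MAE of one default synthetic pipeline."""
    s1, s2, s3 = _child_seeds(seed, 3)
    frame, truth = generate(12, 40, seed=s1)
    table, overall = exceedance_summary(frame)
    split = temporal_split(frame)
    data, scaling = standardize(frame, PREDICTORS, split)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fit(
            build_model(data.train()), chains=chains, draws_per_chain=draws,
            warmup=draws, seed=s2,
        )
    out = {
        "n_sites": overall["n_sites"],
        "pct_sites_ever_exceeded": 100.0
        * overall["n_sites_ever_exceeded"] / overall["n_sites"],
        "pct_sites_median_exceeded": 100.0
        * overall["n_sites_median_exceeded"] / overall["n_sites"],
    }
    for part in ("train", "test"):
        subset = data.subset(data.split_label == part)
        pred = posterior_predict(result, subset, scaling, seed=s3)
        observed = scaling.inverse("Al_i", subset.y)
        mae = mae_with_interval(pred, observed)
        out[f"{part}_mae"] = mae["Q50"]
        out[f"{part}_mae_q2.5"] = mae["Q2.5"]
        out[f"{part}_mae_q97.5"] = mae["Q97.5"]
        out[f"n_{part}"] = mae["n"]
    return out
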