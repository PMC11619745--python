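"""Bayesian linear mixed model for Al_i with one-step imputation.

The response (standardized Al_i) follows a Student-t likelihood around a
linear predictor with per-site random intercepts:

    y_i ~ T(mu_i, sigma, nu),   mu_i = alpha_bar + alpha_site[j(i)] + x_i' beta

Missing and left-censored (nondetect) predictor values are treated as
parameters and sampled from the joint posterior, so every posterior draw
carries its own imputation. Each predictor p has a sub-model

    p ~ T(mu_p, sigma_p, nu_p)

whose location mu_p follows a directed acyclic graph of simple regressions
(DOC drives Al_d, color and Fe_d; Al_d drives Ti_d and pH; Ca_d drives SO4
and alkalinity; F drives Li_d; Fe_d drives Ce_d; DOC, Ca_d and F are
intercept-only; water temperature is a cyclic cubic spline of ordinal day).
Censored cells are constrained to lie at or below their standardized
detection limits.

Priors: residual and sub-model scales half-t(df 3, scale 2.5); degrees of
freedom Gamma(2, 0.1); site intercepts N(0, sigma_alpha); coefficients
beta ~ N(0, tau) with tau ~ half-Cauchy(0, 1) (hierarchical shrinkage that
stabilizes collinear predictors); sub-model coefficients and spline
coefficients N(0, 1) and N(0, sigma_b).

Inference uses a blocked Gibbs sampler built on the normal scale-mixture
representation of the t distribution: conditional on per-observation gamma
mixing weights, every location parameter and every imputed cell has an exact
Gaussian (or truncated-Gaussian) full conditional; scale parameters use the
inverse-gamma auxiliary representation of the half-t prior; the degrees of
freedom take a Metropolis step on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr, ndtri

from .data import ModelData
from .splines import SplineBasis, build_spline_basis

__all__ = [
    "SEASONAL",
    "DEFAULT_GRAPH",
    "ModelSpec",
    "BlmmModel",
    "PosteriorResult",
    "build_model",
    "fit",
    "coefficient_table",
]

#: Sentinel parent marking a seasonal (spline-of-ordinal-day) sub-model.
SEASONAL = "@seasonal"

#: Sub-model graph: predictor -> parent (None = intercept-only).
DEFAULT_GRAPH: dict[str, str | None] = {
    "DOC": None,
    "Ca_d": None,
    "F": None,
    "Al_d": "DOC",
    "Ti_d": "Al_d",
    "color": "DOC",
    "Fe_d": "DOC",
    "Ce_d": "Fe_d",
    "pH_sonde": "Al_d",
    "SO4": "Ca_d",
    "alkalinity": "Ca_d",
    "Li_d": "F",
    "temperature": SEASONAL,
}


@dataclass
class ModelSpec:
    """Structure and prior hyperparameters of the Al_i model."""

    predictors: list[str]
    graph: dict[str, str | None] = field(default_factory=lambda: dict(DEFAULT_GRAPH))
    n_spline_basis: int = 10
    period: float = 365.25
    scale_prior_df: float = 3.0       # half-t df for sigma, sigma_p, sigma_alpha, sigma_b
    scale_prior_scale: float = 2.5    # half-t scale for the same
    nu_prior_shape: float = 2.0       # Gamma prior on degrees of freedom
    nu_prior_rate: float = 0.1
    tau_prior_scale: float = 1.0      # half-Cauchy scale for the shrinkage sd tau
    submodel_coef_sd: float = 1.0     # N(0, 1) prior on sub-model coefficients
    intercept_sd: float = 5.0         # weak prior on the global intercept
    nu_fixed: float | None = None     # fix the likelihood df (Gaussian limit checks)

    def toposort(self) -> list[str]:
        """Dependency-ordered sub-model names; raises on a cycle."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(name: str, stack: tuple[str, ...]) -> None:
            if name in seen:
                return
            if name in stack:
                raise ValueError(f"sub-model graph has a cycle through {name!r}")
            parent = self.graph[name]
            if parent is not None and parent != SEASONAL:
                if parent not in self.graph:
                    raise ValueError(
                        f"sub-model parent {parent!r} of {name!r} has no sub-model"
                    )
                visit(parent, stack + (name,))
            seen.add(name)
            order.append(name)

        for name in self.graph:
            visit(name, ())
        return order


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class _Submodel:
    name: str
    col: int                      # column index in X
    kind: str                     # "intercept" | "slope" | "seasonal"
    parent_col: int | None = None
    basis: SplineBasis | None = None


class BlmmModel:
    """Preprocessed data plus graph structure, ready for sampling."""

    def __init__(self, data: ModelData, spec: ModelSpec):
        data.validate()
        self.spec = spec
        self.data = data
        train = data.train()
        self.train = train
        self.n = len(train.y)
        self.p = len(spec.predictors)
        self.J = data.n_sites

        col = {name: j for j, name in enumerate(spec.predictors)}
        order = spec.toposort()  # validates acyclicity
        self.submodels: list[_Submodel] = []
        for name in order:
            if name not in col:
                continue
            parent = spec.graph[name]
            if parent == SEASONAL:
                basis = build_spline_basis(
                    train.ordinal_day, spec.n_spline_basis, spec.period
                )
                self.submodels.append(_Submodel(name, col[name], "seasonal", None, basis))
            elif parent is None:
                self.submodels.append(_Submodel(name, col[name], "intercept"))
            else:
                self.submodels.append(_Submodel(name, col[name], "slope", col[parent]))

        modeled = {sm.col for sm in self.submodels}
        incomplete = train.missing_mask.any(axis=0) | train.censored_mask.any(axis=0)
        for j, name in enumerate(spec.predictors):
            if incomplete[j] and j not in modeled:
                raise ValueError(
                    f"predictor {name!r} has missing or censored cells but no "
                    "sub-model in the graph"
                )
        self.children: dict[int, list[_Submodel]] = {}
        for sm in self.submodels:
            if sm.parent_col is not None:
                self.children.setdefault(sm.parent_col, []).append(sm)

        # registry of free (imputed) cells, column-major order
        rows, cols = np.nonzero(train.missing_mask | train.censored_mask)
        order_idx = np.lexsort((rows, cols))
        self.cell_rows = rows[order_idx]
        self.cell_cols = cols[order_idx]
        self.cell_censored = train.censored_mask[self.cell_rows, self.cell_cols]
        self.cell_bounds = train.censor_bounds[self.cell_rows, self.cell_cols]
        self.n_cells = len(self.cell_rows)

    @property
    def n_parameters(self) -> int:
        """Sampled parameter count (auxiliary scale-mixture latents excluded).

        Fixed effects p, shrinkage sd tau, global intercept, J site effects,
        sigma_alpha, sigma, nu, each plain sub-model's (coef, sigma_p, nu_p),
        the seasonal sub-model's (gamma, K spline coefficients, sigma_b,
        sigma_p, nu_p), and one parameter per missing or censored cell.
        """
        count = self.p + 1 + 1 + self.J + 3
        for sm in self.submodels:
            if sm.kind == "seasonal":
                count += self.spec.n_spline_basis + 4
            else:
                count += 3
        return count + self.n_cells


def build_model(data: ModelData, spec: ModelSpec | None = None) -> BlmmModel:
    """Assemble the joint model; validates masks, graph acyclicity, coverage."""
    if spec is None:
        spec = ModelSpec(predictors=list(data.predictors))
    if list(spec.predictors) != list(data.predictors):
        raise ValueError("spec predictor order must match the data")
    return BlmmModel(data, spec)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _inv_gamma(rng: np.random.Generator, shape: float, rate) -> np.ndarray | float:
    return rate / rng.gamma(shape, 1.0, size=np.shape(rate) or None)


class _HalfTScale:
    """sigma^2 with a half-t(df, A) prior on sigma, via the IG auxiliary."""

    def __init__(self, df: float, A: float, init: float = 1.0):
        self.df = df
        self.A = A
        self.sigma2 = init
        self.aux = 1.0

    def update(self, rng: np.random.Generator, ss: float, m: float) -> float:
        self.aux = _inv_gamma(
            rng, (self.df + 1) / 2.0, self.df / self.sigma2 + self.A**-2
        )
        self.sigma2 = max(
            _inv_gamma(rng, (self.df + m) / 2.0, self.df / self.aux + ss / 2.0),
            1e-12,
        )
        return self.sigma2


#: Geometric grid for the collapsed degrees-of-freedom update. The Gamma(2,
#: 0.1) prior concentrates on roughly 2-80; the grid spans well beyond both
#: tails and the conditional is sampled piecewise-uniformly within cells.
_NU_EDGES = np.geomspace(1.0, 400.0, 61)
_NU_CENTERS = np.sqrt(_NU_EDGES[:-1] * _NU_EDGES[1:])
_NU_WIDTHS = np.diff(_NU_EDGES)


def _sample_nu(
    rng: np.random.Generator,
    resid: np.ndarray,
    sigma2: float,
    prior_shape: float,
    prior_rate: float,
) -> float:
    """Draw nu from its conditional with the mixing weights integrated out.

    Marginalizing the per-observation gamma weights leaves the exact t
    likelihood of the residuals, so a grid draw here followed by the weight
    update is a blocked (nu, lambda) move — this avoids the notorious random
    walk stickiness of nu against the weights.
    """
    n = len(resid)
    r2 = resid**2 / sigma2
    nu = _NU_CENTERS
    a = (nu + 1.0) / 2.0
    ll = n * (
        gammaln(a) - gammaln(nu / 2.0) - 0.5 * np.log(nu * np.pi * sigma2)
    ) - a * np.sum(np.log1p(r2[:, None] / nu[None, :]), axis=0)
    lp = ll + (prior_shape - 1.0) * np.log(nu) - prior_rate * nu + np.log(_NU_WIDTHS)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    g = rng.choice(len(nu), p=w)
    return float(rng.uniform(_NU_EDGES[g], _NU_EDGES[g + 1]))


def _trunc_norm_upper(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, upper: np.ndarray
) -> np.ndarray:
    """Draws from N(mean, sd^2) truncated to (-inf, upper], vectorized.

    Inverse-CDF sampling with a final clip so the upper bound is a hard
    guarantee even at extreme tail probabilities.
    """
    z_hi = (upper - mean) / sd
    p_hi = ndtr(z_hi)
    u = rng.random(np.shape(mean)) * p_hi
    x = mean + sd * ndtri(np.maximum(u, 1e-300))
    return np.minimum(x, upper)


class _Chain:
    """One Gibbs chain over the joint posterior."""

    def __init__(self, model: BlmmModel, rng: np.random.Generator):
        self.m = model
        self.rng = rng
        spec = model.spec
        train = model.train
        n, p, J = model.n, model.p, model.J

        self.y = train.y
        self.site = train.site_index
        self.Xc = train.X.copy()
        # initialize free cells: missing at the (standardized) mean, censored
        # half a standard deviation below their bound
        mr, mc = np.nonzero(train.missing_mask)
        self.Xc[mr, mc] = 0.0
        cr, cc = np.nonzero(train.censored_mask)
        self.Xc[cr, cc] = train.censor_bounds[cr, cc] - 0.5

        self.alpha_bar = 0.0
        self.a = np.zeros(J)
        self.beta = np.zeros(p)
        self.nu = spec.nu_fixed if spec.nu_fixed is not None else 20.0
        self.lam_y = np.ones(n)
        self.s_sigma = _HalfTScale(spec.scale_prior_df, spec.scale_prior_scale)
        self.s_alpha = _HalfTScale(spec.scale_prior_df, spec.scale_prior_scale, 0.25)
        self.s_tau = _HalfTScale(1.0, spec.tau_prior_scale, 0.25)

        self.sub: dict[int, dict] = {}
        for sm in model.submodels:
            st = {
                "coef": 0.0,
                "nu": 20.0,
                "lam": np.ones(n),
                "scale": _HalfTScale(spec.scale_prior_df, spec.scale_prior_scale),
            }
            if sm.kind == "seasonal":
                st["gamma"] = 0.0
                st["b"] = np.zeros(spec.n_spline_basis)
                st["scale_b"] = _HalfTScale(
                    spec.scale_prior_df, spec.scale_prior_scale, 0.25
                )
            self.sub[sm.col] = st

        # per-column free-cell layout
        self.col_cells: dict[int, dict] = {}
        for j in range(p):
            mask = model.cell_cols == j
            if mask.any():
                self.col_cells[j] = {
                    "rows": model.cell_rows[mask],
                    "censored": model.cell_censored[mask],
                    "bounds": model.cell_bounds[mask],
                }

    # -- conditional means -------------------------------------------------
    def _sub_mu(self, sm: _Submodel, rows=slice(None)) -> np.ndarray:
        st = self.sub[sm.col]
        if sm.kind == "intercept":
            base = np.zeros_like(self.y[rows])
            return base + st["coef"]
        if sm.kind == "slope":
            return st["coef"] * self.Xc[rows, sm.parent_col]
        return st["gamma"] + sm.basis.Z[rows] @ st["b"]

    # -- sweep -------------------------------------------------------------
    def sweep(self) -> None:
        rng = self.rng
        spec = self.m.spec
        n, p, J = self.m.n, self.m.p, self.m.J
        y, site, Xc = self.y, self.site, self.Xc
        sigma2 = self.s_sigma.sigma2

        # blocked (nu, lambda) update: collapsed nu draw, then weights
        r = y - self.alpha_bar - self.a[site] - Xc @ self.beta
        if spec.nu_fixed is None:
            self.nu = _sample_nu(
                rng, r, sigma2, spec.nu_prior_shape, spec.nu_prior_rate
            )
        rate = (self.nu + r**2 / sigma2) / 2.0
        self.lam_y = rng.gamma((self.nu + 1.0) / 2.0, 1.0 / rate)

        w = self.lam_y / sigma2
        # beta | rest
        resid0 = y - self.alpha_bar - self.a[site]
        A = Xc.T @ (Xc * w[:, None]) + np.eye(p) / self.s_tau.sigma2
        b = Xc.T @ (w * resid0)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        self.beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        # global intercept, with the site effects integrated out (the
        # centered pair (alpha_bar, a) otherwise mixes very slowly)
        resid1 = y - Xc @ self.beta
        s_j = np.bincount(site, weights=w, minlength=J)
        m_j = np.bincount(site, weights=w * resid1, minlength=J)
        shrink = 1.0 / (1.0 + self.s_alpha.sigma2 * s_j)
        prec = float(np.sum(s_j * shrink)) + spec.intercept_sd**-2
        lin = float(np.sum(m_j * shrink))
        self.alpha_bar = float(
            lin / prec + rng.standard_normal() / np.sqrt(prec)
        )

        # site effects | alpha_bar
        prec_j = s_j + 1.0 / self.s_alpha.sigma2
        mean_j = (m_j - s_j * self.alpha_bar) / prec_j
        self.a = mean_j + rng.standard_normal(J) / np.sqrt(prec_j)
        self.s_alpha.update(rng, float(np.sum(self.a**2)), J)

        # residual scale
        r = y - self.alpha_bar - self.a[site] - Xc @ self.beta
        self.s_sigma.update(rng, float(np.sum(self.lam_y * r**2)), n)

        # shrinkage scale
        self.s_tau.update(rng, float(np.sum(self.beta**2)), p)

        # sub-models
        coef_prec0 = spec.submodel_coef_sd**-2
        for sm in self.m.submodels:
            st = self.sub[sm.col]
            v = Xc[:, sm.col]
            mu = self._sub_mu(sm)
            s2 = st["scale"].sigma2
            st["nu"] = _sample_nu(
                rng, v - mu, s2, spec.nu_prior_shape, spec.nu_prior_rate
            )
            rate = (st["nu"] + (v - mu) ** 2 / s2) / 2.0
            lam = rng.gamma((st["nu"] + 1.0) / 2.0, 1.0 / rate)
            st["lam"] = lam
            wm = lam / s2
            if sm.kind == "intercept":
                prec = wm.sum() + coef_prec0
                st["coef"] = float(
                    (wm * v).sum() / prec + rng.standard_normal() / np.sqrt(prec)
                )
            elif sm.kind == "slope":
                xp = Xc[:, sm.parent_col]
                prec = (wm * xp**2).sum() + coef_prec0
                st["coef"] = float(
                    (wm * xp * v).sum() / prec
                    + rng.standard_normal() / np.sqrt(prec)
                )
            else:
                # joint (gamma, b) draw: the cyclic basis spans constants, so
                # sequential updates of the level and the spline mix poorly
                Z = sm.basis.Z
                K = Z.shape[1]
                Zg = np.column_stack([np.ones(n), Z])
                prior = np.full(K + 1, 1.0 / st["scale_b"].sigma2)
                prior[0] = coef_prec0
                Ab = Zg.T @ (Zg * wm[:, None]) + np.diag(prior)
                rhs = Zg.T @ (wm * v)
                Lb = np.linalg.cholesky(Ab)
                mean_b = np.linalg.solve(Lb.T, np.linalg.solve(Lb, rhs))
                coefs = mean_b + np.linalg.solve(Lb.T, rng.standard_normal(K + 1))
                st["gamma"] = float(coefs[0])
                st["b"] = coefs[1:]
                st["scale_b"].update(rng, float(np.sum(st["b"] ** 2)), K)
            mu = self._sub_mu(sm)
            st["scale"].update(rng, float(np.sum(lam * (v - mu) ** 2)), n)

        # imputed cells, column by column
        sigma2 = self.s_sigma.sigma2
        w = self.lam_y / sigma2
        sub_by_col = {sm.col: sm for sm in self.m.submodels}
        for j, layout in self.col_cells.items():
            rows = layout["rows"]
            bj = self.beta[j]
            mu_minus = (
                self.alpha_bar
                + self.a[site[rows]]
                + Xc[rows] @ self.beta
                - Xc[rows, j] * bj
            )
            prec = bj**2 * w[rows]
            lin = bj * w[rows] * (y[rows] - mu_minus)
            sm = sub_by_col[j]
            st = self.sub[j]
            w_own = st["lam"][rows] / st["scale"].sigma2
            prec = prec + w_own
            lin = lin + w_own * self._sub_mu(sm, rows)
            for child in self.m.children.get(j, ()):  # j appears as a parent
                stc = self.sub[child.col]
                wc = stc["lam"][rows] / stc["scale"].sigma2
                bc = stc["coef"]
                prec = prec + bc**2 * wc
                lin = lin + bc * wc * Xc[rows, child.col]
            sd = 1.0 / np.sqrt(prec)
            mean = lin / prec
            draw = mean + sd * rng.standard_normal(len(rows))
            cen = layout["censored"]
            if cen.any():
                draw[cen] = _trunc_norm_upper(
                    rng, mean[cen], sd[cen], layout["bounds"][cen]
                )
            Xc[rows, j] = draw


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Draws (chains x draws x ...), imputation registry, and diagnostics."""

    draws: dict[str, np.ndarray]
    predictors: list[str]
    site_labels: list[str]
    cell_rows: np.ndarray
    cell_cols: np.ndarray
    cell_censored: np.ndarray
    cell_bounds: np.ndarray
    imputed: np.ndarray            # (chains, draws, n_cells)
    diagnostics: dict
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.draws["sigma"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["sigma"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def imputed_stacked(self) -> np.ndarray:
        return self.imputed.reshape(-1, self.imputed.shape[-1])

    def censoring_violations(self) -> int:
        """Number of censored-cell draws above their bound (must be zero)."""
        if self.imputed.size == 0 or not self.cell_censored.any():
            return 0
        cen = self.imputed[..., self.cell_censored]
        return int(np.sum(cen > self.cell_bounds[self.cell_censored]))

    def summary(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for name in names or self.draws:
            flat = self.stacked(name)
            if flat.ndim == 1:
                flat = flat[:, None]
                labels = [name]
            elif name == "beta":
                labels = [f"beta[{p}]" for p in self.predictors]
            elif name == "alpha_site":
                labels = [f"alpha_site[{s}]" for s in self.site_labels]
            else:
                labels = [f"{name}[{i}]" for i in range(flat.shape[1])]
            q = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
            for k, lab in enumerate(labels):
                rows.append(
                    {"parameter": lab, "Q2.5": q[0, k], "Q50": q[1, k], "Q97.5": q[2, k]}
                )
        return pd.DataFrame(rows)


def fit(
    model: BlmmModel,
    chains: int = 4,
    draws_per_chain: int = 1000,
    warmup: int = 1000,
    seed: int | None = None,
    rhat_warn: float = 1.01,
) -> PosteriorResult:
    """Run the Gibbs sampler and summarize the joint posterior.

    Defaults retain 4000 draws (4 chains x 1000). The sampler is
    deterministic for a given seed, data and settings. If the rank-normalized
    R-hat of any headline parameter exceeds ``rhat_warn`` a convergence
    warning is emitted (never silent success).
    """
    if seed is None:
        raise ValueError("a seed is required for a reproducible fit")
    spec = model.spec
    p, J, K = model.p, model.J, spec.n_spline_basis
    D = draws_per_chain

    store: dict[str, np.ndarray] = {
        "alpha_bar": np.empty((chains, D)),
        "alpha_site": np.empty((chains, D, J)),
        "sigma_alpha": np.empty((chains, D)),
        "beta": np.empty((chains, D, p)),
        "tau": np.empty((chains, D)),
        "sigma": np.empty((chains, D)),
        "nu": np.empty((chains, D)),
    }
    for sm in model.submodels:
        store[f"sub_{sm.name}_coef"] = np.empty((chains, D))
        store[f"sub_{sm.name}_sigma"] = np.empty((chains, D))
        store[f"sub_{sm.name}_nu"] = np.empty((chains, D))
        if sm.kind == "seasonal":
            store[f"sub_{sm.name}_b"] = np.empty((chains, D, K))
            store[f"sub_{sm.name}_sigma_b"] = np.empty((chains, D))
    imputed = np.empty((chains, D, model.n_cells))

    seeds = np.random.SeedSequence(seed).spawn(chains)
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        try:
            chain = _Chain(model, rng)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise RuntimeError(f"sampler initialization failed: {err}") from err
        for _ in range(warmup):
            chain.sweep()
        for d in range(D):
            chain.sweep()
            store["alpha_bar"][c, d] = chain.alpha_bar
            store["alpha_site"][c, d] = chain.a
            store["sigma_alpha"][c, d] = np.sqrt(chain.s_alpha.sigma2)
            store["beta"][c, d] = chain.beta
            store["tau"][c, d] = np.sqrt(chain.s_tau.sigma2)
            store["sigma"][c, d] = np.sqrt(chain.s_sigma.sigma2)
            store["nu"][c, d] = chain.nu
            for sm in model.submodels:
                st = chain.sub[sm.col]
                store[f"sub_{sm.name}_coef"][c, d] = (
                    st["gamma"] if sm.kind == "seasonal" else st["coef"]
                )
                store[f"sub_{sm.name}_sigma"][c, d] = np.sqrt(st["scale"].sigma2)
                store[f"sub_{sm.name}_nu"][c, d] = st["nu"]
                if sm.kind == "seasonal":
                    store[f"sub_{sm.name}_b"][c, d] = st["b"]
                    store[f"sub_{sm.name}_sigma_b"][c, d] = np.sqrt(
                        st["scale_b"].sigma2
                    )
            imputed[c, d] = chain.Xc[model.cell_rows, model.cell_cols]

    diagnostics = _diagnostics(store, model, rhat_warn)
    return PosteriorResult(
        draws=store,
        predictors=list(spec.predictors),
        site_labels=list(model.data.site_labels),
        cell_rows=model.cell_rows,
        cell_cols=model.cell_cols,
        cell_censored=model.cell_censored,
        cell_bounds=model.cell_bounds,
        imputed=imputed,
        diagnostics=diagnostics,
        spec=spec,
    )


def _diagnostics(store: dict, model: BlmmModel, rhat_warn: float) -> dict:
    import arviz as az

    headline = {
        "beta": store["beta"],
        "sigma": store["sigma"],
        "nu": store["nu"],
        "tau": store["tau"],
        "sigma_alpha": store["sigma_alpha"],
    }
    n_chains = store["sigma"].shape[0]
    diag: dict = {"divergences": 0}  # Gibbs transitions cannot diverge
    if n_chains < 2 or store["sigma"].shape[1] < 4:
        diag.update({"max_rhat": np.nan, "min_ess": np.nan})
        return diag
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=headline)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(
        max(np.nanmax(np.atleast_1d(rhat[v].values)) for v in rhat.data_vars)
    )
    min_ess = float(
        min(np.nanmin(np.atleast_1d(ess[v].values)) for v in ess.data_vars)
    )
    diag.update({"max_rhat": max_rhat, "min_ess": min_ess})
    if max_rhat > rhat_warn:
        warnings.warn(
            f"convergence warning: max R-hat {max_rhat:.3f} > {rhat_warn}",
            UserWarning,
            stacklevel=3,
        )
    return diag


def save_posterior(result: PosteriorResult, npz_path, manifest_path) -> None:
    """Persist draws to .npz plus a JSON manifest of names and model spec."""
    import dataclasses
    import json

    arrays = {f"draw_{k}": v for k, v in result.draws.items()}
    arrays.update(
        imputed=result.imputed,
        cell_rows=result.cell_rows,
        cell_cols=result.cell_cols,
        cell_censored=result.cell_censored,
        cell_bounds=result.cell_bounds,
    )
    np.savez_compressed(npz_path, **arrays)
    manifest = {
        "predictors": result.predictors,
        "site_labels": result.site_labels,
        "diagnostics": result.diagnostics,
        "spec": dataclasses.asdict(result.spec),
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def load_posterior(npz_path, manifest_path) -> PosteriorResult:
    import json

    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    with np.load(npz_path) as arch:
        draws = {
            k[len("draw_"):]: arch[k] for k in arch.files if k.startswith("draw_")
        }
        extras = {
            k: arch[k]
            for k in ("imputed", "cell_rows", "cell_cols", "cell_censored", "cell_bounds")
        }
    return PosteriorResult(
        draws=draws,
        predictors=manifest["predictors"],
        site_labels=manifest["site_labels"],
        cell_rows=extras["cell_rows"],
        cell_cols=extras["cell_cols"],
        cell_censored=extras["cell_censored"].astype(bool),
        cell_bounds=extras["cell_bounds"],
        imputed=extras["imputed"],
        diagnostics=manifest["diagnostics"],
        spec=ModelSpec(**manifest["spec"]),
    )


def coefficient_table(result: PosteriorResult) -> pd.DataFrame:
    """Posterior medians and 95% credible intervals of the fixed effects.

    Rows are ordered by |Q50| descending, matching the presentation of
    standardized-coefficient tables.
    """
    beta = result.stacked("beta")
    q = np.quantile(beta, [0.025, 0.5, 0.975], axis=0)
    table = pd.DataFrame({
        "predictor": result.predictors,
        "Q50": q[1],
        "Q2.5": q[0],
        "Q97.5": q[2],
    })
    order = np.argsort(-np.abs(table["Q50"].to_numpy()), kind="stable")
    return table.iloc[order].reset_index(drop=True)
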