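# Methods

## Scope and data model

The package analyzes long-format water-chemistry monitoring records: one row
per site and date, with in-situ sonde fields (pH, water temperature,
specific conductance) and lab analytes, each analyte carrying a value, a
left-censoring flag, and a detection limit. Cationic aluminum is the
operational difference Al_i = Al_d − Al_o. Negative differences can arise
from measurement noise in the two determinations; they are retained and
flagged rather than deleted, because deletion would bias low concentrations
upward. %Al_i = Al_i/Al_d is reported as missing wherever Al_d is
non-positive, censored, or missing.

Input CSVs accept two censoring conventions — a `<DL` text prefix in the
value column, or companion `<name>_censored` / `<name>_dl` columns — and the
writer emits the `<DL` convention. Dates are ISO-8601 calendar dates;
ordinal day is computed leap-year aware, while the seasonal period is fixed
at 365.25 days.

## Exceedance and trends

Threshold-exceedance summaries use strict inequality (a value exactly at the
threshold does not count as an exceedance) and per-site medians over
non-missing values; sites with no Al_i values are excluded from counts and
reported separately. The default threshold is 15 µg/L, an Al_i level
associated with harm to Atlantic salmon in acidic, dilute waters.

Monotonic trends use the Mann–Kendall test implemented from first
principles: S = Σ_{i<j} sign(x_j − x_i), tau with the tie-corrected
denominator √((D₀ − T)·D₀), and the tie-corrected null variance
[n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18. For n ≤ 10 without ties the exact null
distribution of S is enumerated through the Mahonian inversion-count
recursion; otherwise the normal approximation with continuity correction is
used (small tied series also fall back to the corrected approximation —
their exact distribution depends on the tie pattern and enumeration buys
little). Missing values are dropped with order preserved; the series is
tested as given, with no aggregation of same-day replicates and no seasonal
or autocorrelation-corrected variant. Kendall's tau-b (with the full joint
tie-correction variance) and Pearson's r (t test on n − 2 df) cover
pairwise association; scipy implementations serve as independent oracles in
the tests, never as the implementation.

## Train/test split, screening, standardization

The split is temporal to avoid leakage between dependent observations: per
site with at least 5 observations, the most recent ceil(0.2·n) rows are held
out; smaller sites contribute all rows to training. Ceiling rounding
guarantees every eligible site at least one test row; within-site date ties
are broken by stable input order.

Predictor screening keeps a candidate when its pairwise-complete Pearson
correlation with Al_i in the training set exceeds 0.1 in absolute value
(absolute value, because negatively correlated predictors such as pH belong
in the model), or when it is *supplementary* — required by the
missing-value sub-model system regardless of marginal correlation. The
pipeline defaults the supplementary set to the sub-model graph nodes.
Candidates more than 50% missing-or-censored are dropped unconditionally.
Censored values enter the screening correlation at their detection limit;
this is a pre-model heuristic only, and the model proper treats them as
bounded parameters.

All variables (response included) are standardized to zero mean and unit
standard deviation using observed — non-missing, non-censored — training
entries only, with the n−1 denominator; censored detection limits are mapped
through the same affine transform, and predictions are destandardized back
to µg/L.

## The Bayesian linear mixed model

Likelihood and linear predictor, on the standardized scale:

    y_i ~ T(μ_i, σ, ν),    μ_i = ᾱ + α_site[j(i)] + x_i′ β

The site intercept is parameterized as a global level ᾱ plus zero-centered
site deviations α_site_j ~ N(0, σ_α) — an equivalent parameterization of a
random intercept centered at ᾱ, chosen for sampler health.

Missing and left-censored predictor cells are parameters of the joint
posterior. Each predictor p has a sub-model p ~ T(μ_p, σ_p, ν_p) with

    Al_d = β·DOC        Ti_d = β·Al_d      color = β·DOC     Fe_d = β·DOC
    Ce_d = β·Fe_d       pH   = β·Al_d      SO4  = β·Ca_d     alkalinity = β·Ca_d
    Li_d = β·F          DOC  = α           Ca_d = α          F = α
    temperature = γ + f(t),   f(t) = Z_s b_s  (cyclic cubic spline, ordinal day)

Slope-type sub-models carry no intercept (all variables are standardized);
only the three source variables (DOC, Ca_d, F) are intercept-only, and γ is
the temperature sub-model's intercept. The graph must be acyclic and every
predictor with missing or censored cells must have a sub-model; both are
validated at build time. Censored cells are bounded above by their
standardized detection limit. Because upstream values may themselves be
missing, imputation is joint: a missing DOC value is informed simultaneously
by the response, by its own sub-model, and by every sub-model in which DOC
appears as a parent.

Priors: σ, σ_p, σ_α, σ_b ~ half-t(0, 2.5, 3); ν, ν_p ~ Gamma(2, 0.1);
β ~ N(0, τ) with τ ~ half-Cauchy(0, 1); sub-model coefficients ~ N(0, 1);
spline coefficients b_s ~ N(0, σ_b), which realizes the smoothing penalty as
a hierarchical prior. The global intercept gets a weak N(0, 5) prior.
Response censoring is out of scope: only predictor nondetects are modeled,
and rows without an observed Al_i are dropped (with a warning).

### Sampler

Inference is a blocked Gibbs sampler exploiting the scale-mixture identity
T(μ, σ, ν) = ∫ N(μ, σ²/λ) dGamma(λ; ν/2, ν/2):

- per-observation weights λ ~ Gamma((ν+1)/2, (ν + r²/σ²)/2);
- β, ᾱ, α_site, sub-model coefficients, spline coefficients, and every
  imputed cell have exact Gaussian full conditionals given the weights;
  censored cells use upper-truncated Gaussians (inverse-CDF sampling with a
  final hard clip at the bound, so the constraint holds exactly even at
  extreme tail probabilities);
- scale parameters use the inverse-gamma auxiliary representation of the
  half-t prior (σ² | a ~ IG(ν₀/2, ν₀/a), a ~ IG(1/2, A⁻²)); the half-Cauchy
  on τ is the ν₀ = 1 special case;
- each ν is drawn from its conditional with the weights integrated out
  (the exact t likelihood of the current residuals) on a 60-cell geometric
  grid over [1, 400], sampling piecewise-uniformly within the chosen cell,
  followed by the weight update — a blocked (ν, λ) move that avoids the
  notorious stickiness of random-walk updates for t degrees of freedom;
- the global intercept is drawn with the site effects marginalized out
  (the centered pair otherwise mixes slowly), and the temperature
  sub-model's level and spline coefficients are drawn jointly because the
  cyclic basis spans constants.

Three structural choices — collapsed ν, marginalized intercept, joint
(γ, b_s) — were made after observing slow mixing in those directions;
with them, rank-normalized R-hat on the headline parameters sits near 1.00
at 2 chains × 500 draws. Defaults are 4 chains × 1000 retained draws after
1000 warmup sweeps; a convergence warning (never silent success) is raised
if any headline R-hat exceeds 1.01. Gibbs transitions cannot diverge, so
the divergence count is reported as zero by construction. Chains are seeded
by spawning a SeedSequence from the user seed; identical seed, data and
settings give byte-identical draws. Posterior summaries are empirical draw
quantiles with linear interpolation. The coefficient table is sorted by
|median| descending.

### Spline basis

The cyclic cubic regression spline uses the value-at-knots
parameterization: K evenly spaced knots on [0, 365.25), with the periodic
natural cubic spline interpolating the coefficients; value, first, and
second derivatives match at the period boundary, and a constant coefficient
vector reproduces a constant function exactly. K defaults to 10 (4 minimum)
— enough for one smooth annual cycle with mild asymmetry; the prior on b_s
supplies the penalization, so the exact K is not critical.

## Prediction and evaluation

Posterior prediction for new rows mirrors the fit: per retained draw,
missing new-data predictors are sampled from their sub-models in dependency
order (never plugged in at their means), censored new-data predictors are
sampled from upper-truncated t distributions, known sites use their fitted
intercepts, and unseen sites draw a fresh effect from N(0, σ_α). The
reported error statistic is the median absolute error with a 95% credible
interval: per draw d, median_i |y_i − ŷ_i^(d)|, summarized by the
2.5/50/97.5 percentiles across draws.

Per-draw point predictions ŷ^(d) are the conditional means μ^(d). Adding
fresh observation noise to the point prediction would inflate the median
absolute difference by roughly √2 and could never approach the noise floor
of the generating process; the noisy predictive draws are instead used
where distributional spread is the point — the ECDF overlay (observed curve
plus a sample of predictive curves) and the calibration fraction (share of
observations below their predictive median, ≈ 0.5 when calibrated). The
MAE of the single posterior-median prediction is also reported, labeled as
a secondary summary. MAE pools all sites. Negative predicted concentrations
are possible (the standardized linear model does not enforce positivity)
and are reported as-is.

## Synthetic-data generator

The generator emulates the statistical structure the model assumes, with
known truth for recovery tests: standardized latent variables generated
along the sub-model DAG with t residuals, per-site N(0, σ_α) intercepts, a
seasonal temperature cycle (amplitude 1.1 sd, peak near day 200), and an
affine map to realistic soft-water units (DOC ≈ 13 ± 5.5 mg/L, Al_d ≈
300 ± 110 µg/L, pH ≈ 4.6 ± 0.5, Ca_d ≈ 1.1 ± 0.35 mg/L). Default effect
sizes put dissolved Al dominant (0.79 standardized), DOC negative (−0.33)
*after* conditioning while its marginal correlation with Al_i stays
positive (sub-model slopes were tuned once for that sign pattern), and
smaller effects for the trace metals, fluoride, temperature and the ion
chemistry. Default residuals: σ = 0.4, ν = 15, σ_α = 0.5 (standardized).

Missingness is MCAR per variable (default 8%), with an optional
winter-weighted variant reflecting that ice cover suppresses winter
sampling. Left-censoring replaces values below a known detection limit by
the limit and flags them; default limits are set at the censor-rate quantile
of the variable's marginal (rates nominal at 5–15% and configurable), and
lab-measured analytes are censorable by default while sonde fields are not.
The emitted Al_i column plays the role of the field-speciated
determination: it is consistent with Al_d − Al_o on the true scale, so a
lab-side Al_d nondetect does not destroy the response — mirroring the field
protocol where speciation happens at the riverbank and metals are
re-analyzed in the lab.

What the generator does **not** emulate: discharge dependence (no
hydrograph), informative missingness beyond the seasonal option,
measurement error in the response, drifting detection limits, or spatial
correlation between sites. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data violations of them.

Because both the generator's unit map and the model's standardization are
affine, the true coefficient on the model's scale is computable exactly:
β·(gen_scale_y/gen_scale_x)·(fit_scale_x/fit_scale_y). Recovery tests
compare posterior intervals against this rescaled truth.

## Validation studies and their conditions

The studies module runs: (1) Mann–Kendall against an O(n²) brute-force
oracle on 500 random tied vectors (n ≤ 50); (2) type-I calibration at
α = 0.05 under an iid null (n = 20, 2000 replicates); (3) a 20-replicate
recovery study at 10 sites × 40 observations with 10% missingness and 10%
censoring per predictor, fit with 2 chains × 500 draws after 500 warmup
sweeps — reduced-scale conditions chosen so the full study runs in minutes
on one CPU — checking 95% interval coverage per coefficient and auditing
every censored-cell draw against its bound; (4) the Gaussian limit (ν fixed
at 1000, complete data) against penalized least squares with the fitted
scales; (5) the test-set predictive MAE against the closed-form median
absolute t noise σ·F⁻¹(0.75)·scale; (6) the split/screening rules on data
constructed to satisfy them; (7) spline cyclicity and sine recovery.

Coverage in (3) is nominally 95% per coefficient but is a binomial count
over 20 replicates of a shrinkage estimator at fixed truth, so observed
counts of 18–20 are typical and occasional 16–17s occur, slightly more
often than the pure binomial would suggest for strongly shrunk or strongly
collinear coefficients.

## Manual external check (requires a download)

The study dataset this model family was developed for is publicly deposited
(github.com/bentrueman/al-i-prediction). A manual check, not part of the
test suite because it needs network access: read the deposited CSV with
`read_samples_csv` column-mapping, run the pipeline with default settings,
and compare the top-five coefficient signs and rank order (Al_d, DOC, Ti_d,
Fe_d, F) and the test-set MAE credible interval against the published
values.

## Known limitations

- The sampler is exact-conditional Gibbs, so there are no divergences to
  monitor, but strongly correlated posteriors (e.g., near-collinear
  predictors at small n) mix more slowly than a well-tuned HMC would;
  R-hat/ESS diagnostics are always computed and surfaced.
- Sub-models are simple one-parent regressions; real covariance structure
  richer than the DAG (e.g., joint seasonality of DOC and temperature) is
  absorbed into sub-model residuals.
- The ν grid truncates at 400; likelihoods effectively Gaussian beyond that
  are represented by draws near the upper edge (or fix ν explicitly).
- Predictions assume the new data's chemistry resembles the training
  distribution; the model is not intended for causal interpretation.
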