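# alimix

Analysis toolkit for **toxic cationic aluminum (Al_i) in acidified rivers**:
speciation arithmetic and threshold-exceedance summaries, Mann–Kendall trend
tests, and a fully Bayesian linear mixed model that predicts Al_i from
routinely measured water chemistry while jointly imputing missing and
left-censored (nondetect) predictors.

## The problem

Labile, positively charged aluminum species (Al³⁺, Al(OH)₂⁺, Al(OH)²⁺) are
acutely toxic to salmonids: they bind to gill surfaces and impair
osmoregulation, with juvenile Atlantic salmon most vulnerable during
smoltification. Al_i is measured operationally as the difference between
dissolved aluminum (0.45 µm filtrate) and organically complexed aluminum
(cation-exchange eluate):

```
Al_i = Al_d − Al_o
```

Field speciation is slow and expensive, so it is rarely part of routine
monitoring. The goal of the model here is to predict Al_i from parameters
that *are* routinely measured — dissolved metals, DOC, color, pH, water
temperature, sulfate, alkalinity, fluoride — in acidic, dilute, organic-rich
soft waters, and to quantify how often an assumed toxicity threshold of
15 µg/L is exceeded.

## The model

Standardized Al_i concentrations follow a Student-t likelihood around a
linear predictor with per-site random intercepts:

```
y_i ~ T(μ_i, σ, ν)        μ_i = ᾱ + α_site[j(i)] + x_i′ β
```

Real monitoring data are full of holes and nondetects, and the model treats
both as parameters of the joint posterior (one-step imputation): every
posterior draw carries its own imputed value for each missing cell, and
censored cells are constrained below their detection limits. Each predictor
p has a sub-model `p ~ T(μ_p, σ_p, ν_p)` whose location follows a directed
acyclic graph of simple regressions — DOC drives Al_d, color, and Fe_d; Al_d
drives Ti_d and pH; Ca_d drives SO₄ and alkalinity; F drives Li_d; Fe_d
drives Ce_d; water temperature is a cyclic cubic regression spline of
ordinal day (period 365.25 d). Priors: half-t(3, 2.5) scales, Gamma(2, 0.1)
degrees of freedom, β ~ N(0, τ) with τ ~ half-Cauchy(0, 1) (hierarchical
shrinkage that stabilizes collinear predictors), N(0, 1) sub-model
coefficients, and N(0, σ_b) spline coefficients.

Inference is a blocked Gibbs sampler built on the normal scale-mixture
representation of the t distribution: given per-observation mixing weights,
every location parameter and every imputed cell has an exact Gaussian (or
upper-truncated Gaussian) full conditional; the degrees of freedom use a
collapsed grid update. See `docs/methods.md` for details.

## Worked example

The package ships a synthetic-data generator with the dependence structure
the model assumes and known truth. The pipeline runs end to end from the
command line:

```
alimix simulate --seed 7 --n-sites 10 --n-per-site 40 --output-dir demo
alimix status  --input demo/samples.csv --output-dir demo
alimix fit     --input demo/samples.csv --output-dir demo --seed 7 \
               --chains 2 --draws 500 --warmup 500
alimix predict --input demo/samples.csv --output-dir demo --seed 7
```

`status` reports threshold exceedance — on this synthetic dataset all 10
sites exceed 15 µg/L at least once and all 10 site medians exceed it:

```
{'threshold': 15.0, 'n_sites': 10, 'n_sites_ever_exceeded': 10,
 'n_sites_median_exceeded': 10}
```

`fit` writes the standardized coefficient table (posterior median and 95%
credible interval, ordered by effect magnitude). Dissolved Al dominates,
DOC is negative once the other variables are held fixed, and the trace
metals contribute smaller positive effects — the structure the generator
encodes:

```
predictor,Q50,Q2.5,Q97.5
Al_d,0.701,0.621,0.778
DOC,-0.263,-0.379,-0.148
Ti_d,0.152,0.084,0.216
F,-0.148,-0.222,-0.080
temperature,0.110,0.054,0.160
pH_sonde,0.104,0.030,0.171
```

`predict` scores the temporal train/test split (the most recent 20% of each
site's record is held out) and reports the median absolute error with its
95% credible interval, in µg/L:

```
split,Q2.5,Q50,Q97.5
train,6.40,6.95,7.58
test,6.23,7.59,9.24
```

The test-set error sits at the generator's irreducible noise floor
(σ = 0.4 standardized ≈ 6.1 µg/L median absolute t noise), which is what a
correctly specified fit should achieve.

Every stage is also available as a library call (`alimix.generate`,
`alimix.temporal_split`, `alimix.select_predictors`, `alimix.standardize`,
`alimix.build_model`, `alimix.fit`, `alimix.posterior_predict`, …); see the
module docstrings.

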