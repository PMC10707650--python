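# Methods

## The model

The observable is the radiocesium activity concentration (Bq kg⁻¹) of a
growing shoot — the current-year branch of a hardwood stem, whose
concentration proxies that of the woody stem used for mushroom bed logs.
Concentrations in forest vegetation are well described as log-normal, so the
analysis works throughout on `y = log_e(activity)`.

Individuals are grouped by **stand** (a forest plot of a few tens of m²).
Within stand *s*,

    y_i ~ Normal(mu_s, sigma_s²).

Two structures for the within-stand SD are compared:

* **common-SD model** (`model1`): `sigma_s = sigma_bar` for all stands;
* **varying-SD model** (`model2`): `sigma_s = sigma_bar · exp(eps_V[s])`,
  `eps_V ~ Normal(0, sigma_V²)`.

In both, the stand mean decomposes as `mu_s = mu_bar + eps_M[s]` with
`eps_M ~ Normal(0, sigma_M²)`.  The **all-species model** (`full`) extends the
common-SD structure with a binary stem-origin covariate `O` (0 = coppice
sprout, 1 = plantation) with coefficient `beta`, and a random species effect
`eps_S ~ Normal(0, sigma_S²)`; the species effect lets a species observed
only a handful of times borrow strength from the rest.

Priors: `mu_bar ~ Normal(0, 100²)` and `beta ~ Normal(0, 100²)` (vague);
every SD hyperparameter (`sigma_bar`, `sigma_M`, `sigma_V`, `sigma_S`) gets a
half-normal prior with scale 10 (weakly informative).  The `beta` prior is
not pinned down by the source analysis, which states priors only for the mean
and the SDs; the vague normal mirrors the mean's prior and is recorded in the
run manifest.  "HalfNormal(10²)" is read as scale 10, consistent with
`Normal(0, 100²)` meaning SD 100.

Below-detection ("censored") records are **excluded** before fitting rather
than modelled, because their detection limits vary record by record with
counting time; the exclusion fraction is reported so the reader can judge the
resulting left-tail bias.  Natural logarithms are used everywhere.

## Sampling

No probabilistic-programming backend is required: the package defines the
centered-parameterization log posterior explicitly (`shootcs.models`) and
samples it with an affine-invariant ensemble sampler (emcee).  Design points:

* **Independent ensembles as chains.**  Each requested chain is a separate
  ensemble initialized and seeded independently, so split-R̂ compares
  genuinely independent runs.  `warmup` counts discarded ensemble sweeps;
  `sampling` counts retained draws per chain (post-warmup sweeps flattened
  walker-major).  The default protocol is 4 chains × 8000/8000, matching the
  scale of the original survey analysis; `test_scale` shrinks both for quick
  runs.
* **Analytic collapse of the stand means.**  Ensemble samplers lose
  efficiency quickly with dimension, and the stand-mean effects `eps_M`
  contribute one dimension per stand.  They are therefore integrated out of
  the sampled density in closed form (normal–normal conjugacy gives each
  stand's marginal likelihood analytically), and after sampling every
  retained draw is completed with an exact draw of `eps_M` from its
  conjugate normal conditional.  The composition is an exact draw from the
  full joint posterior — nothing is approximated — but the ensemble now
  walks in 3 dimensions for the common-SD model, ~10 for the all-species
  model, and `4 + #stands` for the varying-SD model (whose `eps_V` has no
  conjugate integral).  Without the collapse, 60-stand varying-SD fits
  showed R̂ of 1.5–1.9 at practical warmup lengths; with it they pass the
  1.1 gate.
* **Unconstrained, non-centered space.**  SDs are sampled on the log scale
  (with the half-normal's Jacobian) and the remaining random effects as
  standardized `z`-scores with `eps = sigma·z`, avoiding the funnel when a
  variance component is near zero.  The collapsed density is pinned to
  `models.log_posterior` in the test suite through the exact identity
  `p(θ) = p(θ, eps_M)/p(eps_M | θ)`, which must hold for *any* `eps_M`.
* **Initialization.**  Walkers start from a moment-based point (pooled
  within-stand residual SD, spread of stand means) with Gaussian jitter.
  This shortens warmup without biasing the stationary distribution; R̂ and
  the convergence gate catch failures.
* **Convergence.**  Split-R̂ in the classic variance-ratio form, threshold
  1.1; the command-line `fit` refuses to report when any R̂ ≥ 1.1 unless
  overridden.

The varying-SD model remains the slowest mixer: on strongly heterogeneous
60-stand data its ensembles need several thousand warmup sweeps to pass the
R̂ gate, versus a few hundred for the collapsed common-SD model.  Posterior
summaries (mean, SD, 2.5%/97.5% quantiles, R̂) pool all chains.

## New-stand WAIC

The model comparison question is predictive: *how well would each model
forecast concentrations in a stand not yet sampled?*  The pointwise
predictive density therefore marginalizes the stand-level effects out of the
likelihood instead of conditioning on the fitted stands:

* common-SD model: closed form, `y_i ~ Normal(mu_i, sigma_bar² + sigma_M²)`;
* varying-SD model: the double integral over `(eps_M, eps_V)` is done by
  Monte Carlo with fresh standard-normal nodes per posterior draw
  (default 1000), combined by log-sum-exp; the integrator is validated
  against the closed form (forced-MC path) and against 2-D Gauss–Hermite
  quadrature.

Species effects and the origin coefficient are *conditioned on* where
present: the stipulated new unit is a stand, not a species.  WAIC is
`-2·(lppd − p_waic)` with `p_waic = Σ_i var_t(log p(y_i|θ_t))` (unbiased
variance).  The selection rule prefers the structurally simpler model when
`|ΔWAIC| ≤ 2` (a conventional noise scale for WAIC differences, and the
regime in which the original comparison adopted the common-SD model at
Δ = 1); otherwise the smaller WAIC wins.

## New-stand prediction and sample size

With the common-SD model adopted, predicting a new stand is conjugate
normal–normal algebra.  After `n` log measurements with sum `Σy`:

    mu_n      = (mu_bar/sigma_M² + Σy/sigma_bar²) / (1/sigma_M² + n/sigma_bar²)
    1/sigma_n² = 1/sigma_M² + n/sigma_bar²
    y_{n+1}   ~ Normal(mu_n, sigma_bar² + sigma_n²)

Replacing the observed mean with a hypothetical true stand mean gives the
*expected* posterior mean as a function of `n` — the shrinkage curve: with
point estimates `mu_bar = 4.92, sigma_bar = 0.74, sigma_M = 1.33` and a true
mean of 10 Bq kg⁻¹ (log 2.30), the expected mean is 2.92 / 2.46 / 2.38 and
the predictive SD 0.98 / 0.81 / 0.78 for n = 1 / 5 / 10.  The flattening of
both curves past n ≈ 5, against measurement cost growing linearly in n, is
what motivates sampling five shoots per stand.  The uncertainty band of the
curve can be formed by pushing posterior draws of
`(mu_bar, sigma_bar, sigma_M)` through the shrinkage formula and taking
2.5%/97.5% quantiles — the natural Bayesian reading of an uncertainty band
on an expected value.  z-quantiles are standard normal (the predictive is
stated as exactly normal, not Student-t).

Scale helpers translate log-scale quantities for users who think
multiplicatively: geometric SD `exp(sigma)` (0.74 → 2.10), fold change
`exp(delta)` (−1 → 0.37), the central 95% individual range
`exp(2·1.96·sigma)` (≈ 18-fold at sigma 0.74), and the model-implied
probability that an individual falls under a regulatory threshold such as
the 50 Bq kg⁻¹ bed-log limit, `Phi((ln T − mu_s)/sigma_s)`.

## Synthetic data

The generator draws exactly the process the models assume: per-stand
`eps_M` (and `eps_V` when `sigma_V > 0`), per-species `eps_S` crossed with
stands (stands contain several species, so species are not nested in
stands), Bernoulli stem origin, normal log concentrations, and left-censoring
below a fixed detection limit.  `default_survey_config()` emulates the
40-stand hardwood survey: five species weighted 184:111:86:30:7, truth at
the all-species posterior point estimates (4.92, 0.74, 1.33, sigma_S 0.62,
beta −0.39), 11 shoots per stand (≈ 453/40), plantation probability 0.25
(plantations are the minority origin in coppice woodland; the source data do
not report the exact share), and a detection limit at the 7.7% quantile of
the marginal activity distribution, computed by root-finding on the
two-component normal-mixture CDF over origin.

What the generator does **not** emulate: record-specific detection limits
(real limits vary with counting time; the generator uses one threshold),
spatial correlation between stands, unequal real-world per-stand sample
sizes (configurable but defaulting to a fixed count, as the per-stand
distribution is not published), and soil-potassium covariates.  Passing
parameter-recovery and selection tests on this generator therefore shows the
estimator and the decision rule work *when the model is true* — not that the
model is right for any particular forest.

## Numerical choices and scaled test settings

* Quartiles for the 1.5×IQR outlier rule use linear interpolation (type-7);
  the convention is unstated in the source, and this is numpy's default.
* Sample SDs use the n−1 denominator; single-record stands report a missing
  SD rather than zero.
* WAIC rejects non-finite pointwise entries, identifying the draw and
  observation.
* Out-of-support SDs make the log prior −∞ rather than raising, so samplers
  can probe freely.
* Tests run at scaled problem sizes chosen to keep the full suite within a
  normal CI budget while leaving the checks sharp: parameter recovery uses
  20 replicates of 40 stands × 10 shoots with 2 chains × 3000/8000
  (coverage observed: 95% per hyperparameter); WAIC selection frequency uses
  10 replicates per condition of 60 stands × 10, common-SD fits at
  2 chains × 2000/3000 and varying-SD fits at 8000 warmup on heterogeneous
  data (3000 on homogeneous), every fit gated on R̂ < 1.1, with draws
  thinned 8× and 1000 MC nodes.  Full-length (4 × 8000/8000) settings
  remain the defaults for real analyses.
* Monte Carlo noise in the varying-SD model's pointwise log densities leaks
  into `p_waic` as spurious variance and biases WAIC *against* that model
  (the common-SD path is noise-free closed form); the log-mean-exp estimate
  of each density is also biased slightly low.  Both effects shrink with
  `mc_samples`; at 1000 nodes on 600 observations the residual penalty is
  about 1–2 deviance units, which the tolerance-2 tie rule absorbs.
* Reproduction of the original survey's posterior table and WAIC pair
  requires its supplementary data file, which has no public accession; the
  corresponding integration tests activate when a user provides the file.

## Known limitations

* Left-censored records are excluded, not modelled; with ~8% censoring the
  fitted overall mean is biased slightly upward and the within-stand SD
  slightly downward relative to a censored-likelihood treatment.
* The ensemble sampler needs generous warmup on larger hierarchies; users
  fitting hundreds of stands may prefer exporting the model to a
  gradient-based sampler (the density contract in `shootcs.models` is
  self-contained for that purpose).
* WAIC's stand-effect marginalization for the varying-SD model is Monte
  Carlo; its error is controlled by `mc_samples` and enters the WAIC
  difference directly, which is one reason the selection rule treats small
  differences as ties.
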