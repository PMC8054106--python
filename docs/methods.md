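# Methods

This note documents the statistical model, the numerical choices behind
its implementation, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Model

Observations are design-weighted proportions `Q_ikt` from survey `i`
in region `k` and year `t`, carried on the empirical-logit scale
`y_ikt = logit(Q_ikt)`:

    y_ikt = alpha + S_kt + Z_ikt
    S     ~ MVN(0, sigma2 * (R_S ⊗ R_T))
    Z_ikt ~ N(0, tau2 / log(n_ikt))

`S` is a mean-zero latent Gaussian field on the K regions × T years
lattice, vectorised region-major/year-minor (flat index `k*T + t`)
throughout the package. The covariance is separable:

- **Spatial factor `R_S`** — a *proper* CAR correlation: the precision
  `D − rho_s * W` (W the 0/1 adjacency, D its row sums) is inverted and
  rescaled to unit diagonal. The proper variant is used because the
  covariance formula requires `R_S` to be a genuine correlation matrix;
  an intrinsic CAR has singular precision and admits none. `rho_s` is
  restricted to (0, 1): within that range the precision is strictly
  diagonally dominant on a connected graph, hence positive definite,
  and the independence (ρ→0) and strong-smoothing (ρ→1) limits behave
  as expected. Connectivity of the region graph is enforced at
  construction.
- **Temporal factor `R_T`** — AR(1), entries `phi**|t−t'|`,
  `|phi| < 1`. The year axis always covers every calendar year in the
  analysis window; years with no survey are prediction targets, not
  gaps.

Multiple surveys observing the same (region, year) cell each contribute
an independent noise term around the shared `alpha + S_kt`; censuses
enter the same way and differ only through their (much larger)
effective sample size.

### Noise model

The observation variance is `tau2 / log(n_eff)` with
`n_eff = (Σw)² / Σw²` the Kish effective sample size of the
contributing respondents. Precision increasing in sample size is the
only sensible orientation — small opportunistic subsamples must be
smoothed harder than censuses — and the logarithmic form keeps the
precision ratio between a 40-respondent cell and a 40 000-respondent
census at about 1:2.8 rather than 1:1000, acknowledging that
between-survey heterogeneity (instrument wording, fieldwork quality)
does not shrink with n. Design information enters *only* through
`n_eff`; no Taylor-linearised design variance is computed. `n_eff ≤ 1`
is a domain error; the microdata estimator drops groups with
`n_eff < 1.5` (near-singletons) with a warning.

### Empirical logit

`y = log(q/(1−q))` with a continuity correction only at the boundaries:
when `q ∈ {0, 1}`, `q* = (q·n_eff + 0.5)/(n_eff + 1)` (half a
pseudo-count on the effective-sample-size scale), flagged `v_floor` for
audit. The correction is minimal-shrinkage: a cell of 10 zeros maps to
`log(0.5/10.5) ≈ −3.04`, not −∞.

### Priors

All configurable; defaults are weakly informative on the logit scale:

| parameter | prior | rationale |
|---|---|---|
| `alpha` | Normal(0, 10²) | spans essentially all prevalences |
| `sqrt(sigma2)`, `sqrt(tau2)` | Half-Normal(0, 5²) | logit-scale SDs above ~5 are implausible |
| `rho_s` | Uniform(0, 1) | full proper-CAR range |
| `phi` | Uniform(−1, 1) | full stationary AR(1) range |

## Sampler

Metropolis-within-Gibbs, fully reproducible given a seed:

1. **Latent field** — the full conditional of `vec(S)` is Gaussian with
   precision `(R_S⁻¹ ⊗ R_T⁻¹)/sigma2 + diag(Σ_i log(n_i)/tau2)` and is
   sampled exactly by one Cholesky factorisation per iteration. The
   prior precision is assembled from the two small factor inverses
   (`R_S⁻¹ = diag(d)(D − ρW)diag(d)` with `d` the CAR scale factors;
   `R_T⁻¹` the closed-form AR(1) tridiagonal), never by inverting a
   KT×KT covariance. The joint update avoids the slow mixing of
   single-site field samplers.
2. **Intercept** — conjugate Gibbs (Gaussian prior × Gaussian
   likelihood).
3. **Hyperparameters** — random-walk Metropolis on unconstrained
   transforms (`log sigma2`, `log tau2`, `logit rho_s`, `atanh phi`)
   with the corresponding Jacobians. Proposal scales adapt during
   burn-in only (Robbins–Monro toward 0.44 acceptance, step
   `min(0.25, it^-0.6)`) and are frozen afterwards so the retained
   chain satisfies detailed balance. Post-burn-in acceptance outside
   [0.05, 0.8] triggers a warning.

Field prior densities inside the Metropolis steps use the Kronecker
identities (log-determinant from the factor determinants, quadratic
form as `tr(R_S⁻¹ S R_T⁻¹ Sᵀ)/sigma2`), so no dense KT×KT matrix is
ever formed for the prior itself; only the field update's conditional
precision is dense, which is exact and fast at the problem sizes this
package targets (KT ≈ 10³ at most).

The default schedule is 110 000 iterations / 10 000 burn-in / thin 10,
retaining exactly 10 000 draws. The schedule validator requires
`(n_iter − burn_in)/thin` to be a positive integer.

Prediction: per retained draw, `Q_kt = expit(alpha + S_kt)` for every
cell including unobserved ones; summarised by the mean and 2.5%/97.5%
quantiles. A cell's posterior interval widens monotonically as its
observations' `n_eff` falls, and with fixed hyperparameters the
single-cell posterior matches the conjugate-normal closed form (both
are tested).

## Validation

A single random hold-out of 10% of *observations* (not region-years —
a twice-surveyed cell can keep one observation), `round(0.1·N)` with
banker's rounding, unstratified. The model is refit on the remainder
and held-out weighted proportions are compared with the posterior mean
at their cells: Pearson correlation, MAE and RMSE on the proportion
scale (the reporting scale; logit-scale metrics would overweight
extreme prevalences). Constant predictions leave the correlation
undefined: it is reported as NaN with a warning, MAE/RMSE unaffected.

## Reporting

- **Change between anchor years** (percent scale): absolute change
  `end − start` in percentage points; percentage change
  `100·(end−start)/start`, flagged undefined at `start = 0`. Posterior
  intervals are computed draw-wise from paired draws, which preserves
  the posterior dependence between the two years. The absolute point
  estimate equals the change of posterior means (linearity); the
  percent point estimate is the ratio of means, which differs from the
  mean of per-draw ratios — the former is reported. Display rounding is
  1 decimal; unrounded values are retained. The reporter always
  recomputes changes from endpoints rather than trusting any published
  change column, since printed changes are occasionally inconsistent
  with their own printed endpoints.
- **Octile ranking**: eight fixed 12.5-point classes of the 0–100
  scale (`class = 1 + floor(v/12.5)`, capped at 8), *not* empirical
  octiles, so classes are comparable across years. Boundaries belong to
  the upper class (12.5 → class 2). Factors without a natural 0–100
  range are min–max rescaled across regions first. For factors where
  high values are unfavourable the class is flipped to `9 − c`, so
  class 1 always marks the unfavourable end; the orientation map is a
  user-supplied flag, favourable-high by default.
- **Coverage bands**: low < 35, moderate 35–65 (closed interval, as
  conventionally printed), high > 65.

## Synthetic-data generator

The generator exists to make every stage testable against a known
truth. It emulates the *structure* of a national survey archive:

- a connected planar-like region graph (random geometric graph plus its
  Euclidean minimum spanning tree);
- a latent surface drawn from the model's own Kronecker prior via the
  factor Cholesky roots;
- surveys of three families with realistic recall behaviour: event
  years spread over each survey's recall window, DHS-like 3 years,
  MICS-like 2, censuses current-year;
- cluster sampling artefacts: respondents grouped in clusters of ~25
  sharing a log-normal design weight (mean 1, CV 0.5 by default), which
  makes Kish `n_eff < n`;
- partial coverage: surveys skip regions, leaving ≥10% of region-years
  with no observation in the reference scenario, so prediction at
  unsampled cells is always exercised.

The **reference scenario** is K=12 regions × T=10 years with truth
`alpha=−0.5, sigma2=1.0, rho_s=0.9, phi=0.8, tau2=1.5` — strong spatial
and temporal dependence of the kind subnational indicator series
exhibit — and seven surveys (3 DHS-like, 3 MICS-like, 1 census) with
per-region targets of 30–800 respondents (censuses 400–800), matching
the order of magnitude of county-level survey subsamples. A second
generator (`simulate_logit_observations`) draws observations directly
from the Gaussian observation model; it is used for interval-calibration
studies, where the noise model must hold exactly.

What the generator does **not** emulate — and what passing tests
therefore cannot certify about real data: real administrative
geographies and population sizes; systematic between-instrument bias
(question wording, seasonality of fieldwork); informative missingness
(surveys skipping regions *because* of conflict or remoteness — here
coverage gaps are random); respondent-level covariate structure; and
outcome misclassification or recall bias beyond the window filter.
Binomial microdata also mean the Gaussian logit-noise model is only an
approximation in the end-to-end tests; hyperparameter recovery of
`alpha`, `sigma2`, `phi` is demonstrated under that misfit, but `tau2`
absorbs the approximation and is not interpretable as a recovery
target.

## Problem sizes in the tests

The test and acceptance runs use deliberately reduced MCMC schedules,
chosen as the smallest runs whose Monte-Carlo error is negligible
relative to the quantity under test: 21 000/1 000/thin 2 (10 000
retained draws) for hyperparameter recovery on the reference scenario;
6 000/1 000/thin 5 for hold-out validation and the smoothing-vs-raw
RMSE comparison, where only posterior means matter; 3 000/600/thin 6
per replicate for the 100-replicate calibration study at K=6, T=6. The
production default (110 000/10 000/10) is validated as configuration
arithmetic and used for real analyses.

## Known limitations

- No covariates: the smoother is purely structural; factors driven by
  sharp policy discontinuities will be over-smoothed across the break.
- A single chain; convergence is assessed by acceptance-rate monitoring
  and the recovery/calibration test battery rather than multi-chain
  diagnostics (the draw store is plain arrays and can be inspected with
  `arviz` if desired).
- The dense field update is cubic in K·T; fine time resolutions or
  thousands of regions would need an iterative or sparse solver.
- The separable covariance cannot represent space-time interaction
  (e.g. an epidemic wave moving across regions changes the effective
  temporal correlation locally).
- Hold-out validation is unstratified; with few surveys the held-out
  set can under-represent a survey family.
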