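# Methods

This note documents the models, the numerical choices and the synthetic
study design behind `ricenc`, and what the passing test suite does and
does not demonstrate about real trial data.

## The dilution model and its statistics

The critical N concentration is modelled as `N_C = a · DW^(−b)` with
`a > 0` (plant N% at 1 t ha⁻¹ dry matter) and `0 ≤ b < 1` (dilution
exponent). Fitting is nonlinear least squares **on the original scale**,
initialized from ordinary least squares of `log N_C` on `log DW`; the
log-log fit is used only for initialization because the final estimate
should weight absolute N% errors, matching the convention of the
critical-N literature. Convergence tolerances are 1e-8 on parameters,
residuals and gradient, with at most 500 function evaluations. Flat
data legitimately return `b = 0` with `a` equal to the mean
concentration.

Shared statistics: SD uses the n−1 denominator; CV = SD/mean;
fluctuation range = (max − min)/mean; RRMSE = RMSE divided by the mean
of the measured values. R² is implemented as the **squared Pearson
correlation** between estimated and measured values — the definition
consistent with its use for validation scatter — rather than the
regression-sum-of-squares form; for perfectly linear (even inverted)
relations both give 1, but the correlation form is symmetric in its
arguments and bounded in [0, 1].

Growing degree days use the **mean-temperature convention**
`GDD = (T_max + T_min)/2 − T_B` with `T_B = 12.5 °C` for japonica rice,
and negative daily values are clamped to zero (configurable). The
difference form `(T_max − T_min)/2 − T_B` sometimes seen in print is
not used: it would make thermal time independent of absolute
temperature. Stage windows ("-T" = tillering end, "-V" = vegetative
period) are taken from the sampling-stage labels of the input table,
never inferred from thermal time.

## Synthetic trial design (the study conditions)

The generator emulates a multi-experiment trial series:

* **29 groups** (cultivar × region × year × management combinations),
  each with a true curve drawn from a ~ N(3.56, 0.21) and
  b ~ N(0.34, 0.08), truncated to a ∈ (0, 6) and b ∈ (0, 1) — the
  observed japonica population and the prior supports.
* **N rates 0/135/270/405 kg N ha⁻¹**, 3 replicates, 5 sampling dates
  (tillering → heading).
* **Plateau biomass** follows a logistic trajectory between 0.5 and
  12 t ha⁻¹ in date index, jittered ±8 % (lognormal) per group. No
  mechanistic growth model is claimed; only the biomass span matters
  for curve identification.
* **Plot response** is linear-plus-plateau: each treatment targets a
  plant N% at a fixed multiple (0.6 → 1.3, evenly spaced across rates)
  of that date's critical value, guaranteeing both limiting and
  non-limiting treatments at every date; realized biomass is
  `B_j − S_j · max(0, N_c,j − N%)` with the slope set so that the most
  deficient treatment loses 90 % × (deficit/N_c,j) of the plateau.
* **Noise** is additive Gaussian: biomass SD 0.1 t ha⁻¹ and N% SD
  0.08 % by default (roughly the replicate scatter of destructive
  sampling); recovery tests use 0.01/0.02 so that biomass noise stays
  within 2 % of the smallest (tillering) plateau.
* **Raw measurements**: per-tiller organ weights, tiller density, leaf
  area and N% are back-computed so the indicators module reconstructs
  the intended biomass exactly; organ partitioning shifts from leaf- to
  spike-dominated across dates.

The 14-indicator feature table links PH (linear), SLA-T (saturating)
and DW-V (linear) to the true *a*, and AGDD-T, SLR-T and LAI-V to the
true *b* through **convex-exponential, mutually correlated links** —
real thermal and partitioning indicators co-vary strongly, and no
linear combination of similarly convex features can reproduce a linear
target without amplifying noise, which is exactly the regime where a
random forest outperforms multiple linear regression. TGW and AC are
generated independent of both parameters as negative controls; the
remaining indicators carry weak links. With `feature_noise_sd = 0` the
designated links are exact.

What the generator does **not** emulate: soil N dynamics, spatial
(plot-position) correlation, measurement error correlated across organs
or dates, lodging/pest damage, or genuine phenology differences between
groups. Passing recovery tests therefore show the estimators are
correct under the stated data model, not that real japonica trials meet
that model.

## SDM route

Classification is an LSD-style comparison against the highest-biomass
treatment: the overall one-way ANOVA must be significant (α = 0.05,
pooled within-treatment error variance), then each treatment whose mean
biomass is significantly below the top treatment's (one-sided t at α)
is N-limiting. Zero-variance (degenerate) data fall back to exact mean
comparison; dates with no limiting (or no usable) split are skipped
with a logged reason, never imputed.

The critical point uses the closed-form two-step intersection — OLS of
biomass on N% over limiting treatment means, plateau as the mean
biomass of non-limiting treatments — rather than joint segmented least
squares, matching the linear-plateau wording and keeping the noise-free
case exact. Points whose critical N falls outside the observed N range
of their date ± 50 % are flagged as extrapolated and excluded from the
pooled power fit by default (they remain in the emitted table); without
this quality control a handful of unstable early-season intersections
dominates the mixed curve. Uncertainty comes from a case-resampling
bootstrap (1000 resamples, percentile band over a 50-point biomass
grid); degenerate resamples are skipped and counted.

## BHM route

Likelihood: `DW_ij ~ N(B_j − S_j · max(0, a·B_j^(−b) − N_ij), σ)` per
date *j*. Priors: a ~ U(0, 6), b ~ U(0, 1); weakly informative
data-scaled uniforms for nuisances — B_j ~ U(0, 2·max DW at date j),
S_j ~ U(0, 5·max DW), σ ~ U(0, max(2, 2·SD of all DW)).

The sampler is a hand-rolled adaptive Metropolis-within-Gibbs:
per-parameter Gaussian random walks whose scales adjust every 50
iterations toward 20–50 % acceptance during the adaptation phase and
are frozen afterwards. Because *a* and *b* are strongly ridge-correlated
(the data pin N_C at the observed biomass range, not *a* and *b*
separately), an additional **joint ridge move** proposes `b → b + δ`
with `a → a·c^δ`, which keeps N_C fixed at a pivot biomass *c*; the
pivot is re-estimated during adaptation from the empirical regression
of log *a* on *b*, and the proposal's log-scale asymmetry is corrected
with a `log(a'/a)` term. Without this move, chains at a
5,000 + 5,000-iteration budget show R-hat ≈ 1.6; with it, ≈ 1.02.
Chains initialize from data-informed values (plateau at the date
maximum, slope from each date's biomass~N% regression, *a* near the
N% of samples closest to 1 t ha⁻¹) with per-chain jitter. Convergence
is monitored by the Gelman–Rubin statistic on *a* and *b* across
chains (warning above 1.1); zero post-adaptation acceptance raises an
error.

Default budgets are the full 50,000 + 50,000 iterations (3 chains,
thinning 10); the test suite and the per-group specific-curve fits use
scaled-down budgets (5,000 + 5,000 for calibration; 2,000 + 2,000 × 2
chains for 29-group runs) chosen so the whole suite stays fast while
the calibration property (≥ 90 % empirical coverage of nominal 95 %
intervals) still holds.

The universal posterior is the **equal-quota pooled mixture** of the 29
group posteriors (the same number of evenly spaced draws from each
group), not a single joint fit — consistent with the wide gap between
the pooled Mean and the pooled MPN that motivates reporting the MPN in
the first place. The MPN is the argmax of a Gaussian KDE (Silverman
bandwidth) evaluated on a 512-point grid over the draw range, ties
broken toward the smaller value; constant samples short-circuit.

## Estimation route

Screening is univariate correlation-R² per indicator (constant
indicators report 0 with a degeneracy flag); the top three per target
are kept, ties broken by the fixed indicator column order. MLR is
ordinary least squares; RF is scikit-learn's
`RandomForestRegressor` (bootstrap-aggregated trees, 500 trees by
default, `max_features = mtry`), seeded for reproducibility. LOOCV
predicts every record exactly once from a model trained without it;
`mtry = "auto"` scans 1..k predictors and keeps the smallest LOOCV
RRMSE (smaller mtry on ties). Universal parameters are arithmetic means
of per-group estimates. Group comparison uses the 95 % interval of the
difference of per-level draws (seeded resampling to equal length) and
the standard insert-and-absorb compact-letter construction.

## NNI validation

Each sample's NNI is computed once with the universal curve and once
with its group's specific curve (the reference, which on synthetic data
may be the generator's true curves); agreement is the correlation-R²
and RRMSE over samples. The three-way diagnosis uses a configurable
neutrality band (default ±0.05 around NNI = 1); the band is a practical
convenience — a strict trichotomy at 1 is recovered with `band = 0`.

## Known limitations

* The SDM mixed curve is biased upward at realistic noise because the
  critical N is a ratio of noisy regression quantities (Jensen effect);
  the NNI validation is robust to this, parameter recovery is not —
  hence recovery is only asserted at low noise.
* The BHM assumes homoscedastic biomass noise across dates; real
  replicate scatter grows with biomass.
* The compact-letter comparison treats draws from different levels as
  independent; levels sharing data would need paired comparisons.
* The feature table is a statistical stand-in: its links are chosen to
  produce realistic screening behaviour, not derived from crop
  physiology.
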