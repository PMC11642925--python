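# Methods

This note documents the models implemented in `simbaref`, the choices made
where the design was genuinely open, and what the simulation results do and
do not demonstrate.

## Kinetic forward models

All curves are handled in a closed-form basis of polynomial-times-
exponential terms with an onset time t0 (`simbaref.curves.ExpMixCurve`):
sums of `D^n exp(-lambda D)` with `D = t - t0`, identically zero for
`t <= t0`. This family is closed under convolution with a single
exponential, which is the only convolution reference-tissue models require,
so every model prediction is an exact analytic evaluation. Repeated rates
(|difference| < 1e-6 /min, below float noise for physiological rates) are
handled by the polynomial limit term `D^{n+1}/(n+1) exp(-lambda D)`, never
by failure. Units are minutes and 1/min throughout; activities are any
consistent concentration unit (only ratios enter the PK parameters).

**Reference curve (Feng-1TC).** The reference-region TAC is modelled as a
tri-exponential input shape with a linear rise,

    (A1*D - A2 - A3) e^{-l1 D} + A2 e^{-l2 D} + A3 e^{-l3 D},

convolved with a one-tissue impulse response `K1ref exp(-k2ref t)` — nine
free parameters including t0. These parameters are descriptive, not
biological: distinct parameter sets can produce near-identical curves, and
only the curve matters downstream. The (A2, l2)/(A3, l3) pair is an exact
symmetry of the form, so construction canonicalises l2 >= l3 by swapping;
l1 >= l2 is encouraged by the default fit bounds rather than enforced,
since no symmetry could repair a violation.

**SRTM.** `CT = R1*CR + (k2 - R1*k2a) * (CR (x) e^{-k2a t})` with
`k2 = R1*k2prime`, `k2a = k2/(1+BPND)`. **FRTM.** From the Laplace-domain
identity `CT = R1 (s+k2prime)(s+k3+k4) / ((s+alpha)(s+beta)) CR` with
`k3 = BPND*k4`, `alpha*beta = k2*k4`, `alpha+beta = k2+k3+k4`; degenerate
roots use a repeated convolution. FRTM reduces exactly to SRTM at BPND = 0,
which the tests assert to 1e-10. Model values are taken at frame midpoints
by default; exact frame-integral averaging (the analytic integral of the
basis) is available via `frame_average=True`. Batch versions evaluate all
TACs of a dataset in a handful of numpy broadcasts and agree with the
scalar path to ~1e-13; both agree with a trapezoidal numeric-convolution
oracle to better than 1e-4 relative error.

## Reference fitting

Nine parameters against ~38 frames is deliberately over-parameterised, so
the fitter targets the curve, not the parameters: bounded multi-start
trust-region least squares (weights proportional to frame duration by
default, matching count statistics where longer frames average more decay
events; uniform weighting is available). Default bounds are generous
physiological envelopes scaled to the data (e.g. A1 up to 10x the peak,
t0 at most the first-peak time, l1 in [0.5, 20] /min, l3 in [1e-4, 0.2]
/min). The first start is data-driven (peak height/time and the terminal
washout slope); subsequent starts are uniform draws inside the bounds,
deterministic given the seed. Automated *underfit detection* replaces
visual inspection: a fit is flagged when R-squared < 0.99 (strict
inequality) or the longest run of same-sign residuals exceeds 8 frames —
the signature of a curve that misses the data shape. The first start
passing the check is accepted; otherwise up to 20 restarts, then the
best-RSS fit with the flag raised. On noiseless data the fitted curve
reproduces the input to <0.1% relative RMS; on noisy libraries the refit
curves are closer to the truth than the noisy data (the parametric fit
denoises).

## The hierarchical model

Each log PK parameter (logR1, logk2prime, logBPND; optionally logk4 for the
FRTM variant) has a linear predictor with a global intercept, fixed-effect
covariates, and partially pooled deviations for subject, region and TAC
(subject x measurement x region; repeated measurements get their own TAC
deviations). Subject and TAC deviation vectors are multivariate normal
with estimated covariance (separated into SDs with half-normal priors and
correlation matrices with LKJ(2) priors via the canonical-partial-
correlation transform). Regional differences in logR1 and logBPND are
anatomically heterogeneous, so they enter as unpooled dummy covariates
(weakly informative N(0, 2.5) priors); regional variation in logk2prime —
theoretically absent, empirically small — is instead partially pooled
toward zero. Measurement error is modelled on log sigma with a global
level, subject and region deviations (no TAC-level sigma deviations),
coefficients on centred log frame duration, log region volume and log
injected dose, and a low-rank cubic B-spline smooth over frame time (8
basis functions, centred columns, ridge N(0, 0.5) priors).

Default priors (configurable): intercepts N(mu0, 0.25) with mu0 required
configuration — moderately informative so chains start in the right
neighbourhood; subject/region SDs half-N(0, 0.3) for logR1 and logBPND and
half-N(0, 0.1) for logk2prime; TAC SDs half-N(0, 0.025); centre,
centre x region and age coefficients N(0, 0.1); diagnosis and treatment
coefficients N(0, 0.05); logk4 prior centred at log 0.05 with SD 0.25. The
log-sigma intercept prior is centred, by default, at a data-scale
heuristic (log of 5% of the mean peak activity) with SD 1.5 — a pragmatic
scale-setting device, configurable when the activity units are known. All
deviation blocks are non-centred (standard-normal z-scores scaled by the
hierarchy SDs), avoiding the funnel geometry that the tightly regularised
TAC block would otherwise create.

### Sampling

The posterior is sampled with a blocked adaptive Metropolis scheme designed
around the model's structure:

* TAC-, subject- and region-level z-blocks are conditionally independent
  across their groups given the rest of the state, so each sweep proposes
  and accepts them *in parallel* using a few vectorised forward-model
  evaluations (per-group acceptance from per-TAC likelihood sums).
* Global blocks — intercept-plus-fixed-effects per PK parameter, the
  hierarchy scale/correlation blocks, the sigma model — use multivariate
  random-walk proposals whose covariance is adapted during warmup
  (Haario-style) and frozen afterwards.
* Two families of likelihood-invariant *interweaving* moves repair the
  notorious couplings of hierarchical models: recentering moves translate a
  fixed effect while compensating in the deviation z-scores (theta, and
  hence the likelihood, unchanged; prior-only Metropolis ratio), and
  rescaling moves move a log hierarchy SD while transforming the z-scores
  to keep the deviations fixed (with the exp(-G*delta) Jacobian of the
  transformation). These moves cost no likelihood evaluations and are
  repeated several times per sweep (default 8); without them the
  intercepts and hierarchy SDs mix an order of magnitude more slowly.

Step sizes adapt by Robbins-Monro during warmup toward target acceptance
rates (0.3 for parallel blocks, 0.25 for joint blocks, 0.44 for scalar
interweaving moves) and are frozen for the sampling phase, preserving
detailed balance for the recorded draws. Defaults are 3 chains of 1000
warmup + 1000 sampling sweeps; everything is deterministic given the seed.
Convergence is reported as split-Rhat and bulk ESS (via arviz) for all
scalar summaries, plus per-block acceptance rates; warnings surface for
Rhat > 1.05 or acceptance < 0.05. Non-finite forward predictions evaluate
to log-density -inf and are rejected. Chains can be warm-started from
per-TAC NLS medians (intercepts and region dummies only; priors untouched).

Pointwise log-likelihoods (per frame of per TAC) are stored, and the
effective number of parameters is estimated as PSIS-LOO p_loo (validated
against brute-force leave-one-out on a conjugate toy model within 10%).
Per-TAC complexity is the total divided by the number of TACs.

## Synthetic data

The generator emulates a realistic two-group pre/post study:

* **Reference library.** Feng-1TC parameter sets are sampled with
  replacement from a base set of three plausible cerebellum-like fits
  (peaks ~5-9 units within the first minutes of a 93-min, 38-frame
  schedule). Noise is layered in log sigma: per-frame offsets from the
  frame-duration coefficient and a smooth-over-time bump; a mean reference
  noise scale (default log 0.15 — the reference region is large, hence
  quieter than typical target regions); a measurement-to-measurement
  normal deviation (SD 0.2); all summed before drawing per-frame Gaussian
  noise. Every noisy curve is refit; failures retry with fresh noise (cap
  5). Each entry keeps the *true* parameters/curve, the noisy curve, and
  the *estimated* parameters — target data are generated from the truth
  while downstream fitting sees the estimate, exactly as in real analyses.
* **PK hierarchy.** Nine regions with fixed mean logR1/logBPND spanning an
  order of magnitude in binding (OC 3.0 down to DBS 0.30, the small
  2-mL low-binding brain-stem analogue), global mean k2prime 0.09 /min with
  small fixed regional offsets; multivariate normal subject deviations
  (SDs 0.05/0.10/0.20 for logR1/logk2prime/logBPND, correlations 0.3-0.5)
  and independent TAC deviations (SDs 0.02/0.02/0.03) redrawn per
  measurement. Patients sit 0.08 lower in mean logBPND; active treatment
  adds +0.04 at the post measurement; placebo adds zero.
* **Target noise.** The same structured log-sigma model (base scale
  log 0.30, duration coefficient -0.5 as for counting statistics, volume
  coefficient -0.3, dose coefficient -0.2, early-scan smooth bump, and
  subject/region/measurement deviations); region volumes and injected
  doses are log-normal around per-region and per-study means.

All values were fixed once on physiological plausibility grounds. Under
them, pooled per-TAC NLS correlates with the true BPND at ~0.77-0.81 in the
DBS analogue (where the method has the most to gain) and >0.99 in large
high-binding regions.

What the generator does **not** emulate: image reconstruction and
resolution effects, motion, regional spill-over, frame-schedule
heterogeneity across centres (the packed likelihood requires a common
schedule), or between-centre parameter shifts (the covariate machinery for
centre harmonisation is implemented and tested on relabelled data, but the
default generator produces one centre). Passing tests therefore show
correctness of the statistical machinery under its assumed data-generating
process plus realistic reference-curve estimation error — not robustness
to the full physics of real PET data.

## Evaluation

Accuracy is RMSE (absolute) and Pearson correlation (relative) per region
and parameter on the natural scale, conventionally over the baseline
measurements of the control group; a log-scale variant is available. RMSE
reductions are `100*(1 - RMSE_a/RMSE_b)`, summarised by unweighted mean and
median over regions. The conventional inferential comparator is a linear
mixed model on logBPND (group, time, group x time, region fixed effects;
subject random intercepts; REML via statsmodels) whose group x time
coefficient is the difference-in-differences contrast, with Wald-z
p-values — at the designs used (hundreds of observations) the difference
from a degrees-of-freedom-corrected test is negligible. The hierarchical
model's decision statistic is the posterior mean over posterior SD of the
contrast against a two-sided 1.96 threshold.

Power and false-positive rates over replicates are tail masses of a
penalised **natural** log-spline density (cubic B-splines on quantile
knots over the data range, second-derivative-free at the boundaries so the
log-density continues linearly and the tails are exponential; ridge
penalty 1.0 on second differences of the coefficients; normalisation by
quadrature on a grid extended 8 SDs through the linear-tail region). The
natural-tail constraint matters: an unconstrained basis flattens in the
tails and overestimates tail mass by ~30% on standard-normal benchmarks,
while this estimator is unbiased to within ~0.005 at 500 replicates.
Bootstrap (200 resamples) gives 95% confidence intervals; degenerate or
failed fits fall back to the exact exceedance proportion with a
normal-approximation interval, flagged. The exact proportion is always
reported alongside.

## Problem sizes and calibration caveats

The shipped checks run at desk scale by choice: a 50-curve reference
library, one n=10-per-group, 3-region dataset with 2 chains of 600+600
sweeps for the accuracy comparison, 300 pooled estimates for the DBS
correlation, 500 replicates for the mixed-model null calibration, and 20
small replicates for credible-interval calibration. The full-magnitude
grid (nine regions, n up to 40, the paper-style replicate counts) is in
`scripts/full_scale_study.py` and takes hours to days.

Two caveats established during development and worth knowing:

* **Reference-estimation error is a measurement-level error source.**
  Fitting with the *estimated* reference curve (as any real pipeline must)
  injects an error shared across all regions of a measurement that the
  model's error structure does not represent. With very few subjects per
  group it visibly widens the sampling distribution of the treatment
  contrast relative to the posterior, costing nominal credible-interval
  coverage; under matched conditions (true reference parameters,
  generative TAC SD inside the prior scale) coverage is nominal. A
  measurement-level random effect would be the natural extension.
* **Shrinkage is only as calibrated as the hierarchy scale.** The default
  generator deliberately sets the TAC-level SD for logBPND (0.03) slightly
  above the 0.025 prior scale; posterior deviation SDs then legitimately
  sit slightly above 0.025, and in regions where per-frame noise leaves
  per-TAC NLS nearly optimal the pooling gain is marginal (occasionally
  negative within the sampling noise of a 10-point RMSE). The large gains
  concentrate exactly where the method is needed: small, low-binding,
  noisy regions.

## FRTM variant

The model supports logk4 as a fourth PK parameter (prior centred at
log 0.05 /min, SD 0.25) behind the `pk_parameters` specification. The
forward machinery is fully tested (nesting, numeric oracles); the
simulation study and default specifications use the SRTM, which describes
the simulated data well — four-parameter reference models are known to be
hard to identify even with pooling.
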