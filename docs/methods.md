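# Methods

This note documents the models, numerical choices and limitations behind
`cgmard`.  Glucose is mg/dL throughout; time is minutes from run start;
MARD-type quantities are percent.

## Metrics

`ARD_k = 100 |y_CGM - y_ref| / y_ref`, `MARD = mean(ARD)`.  The mean (never
the median) is the default statistic; a median option exists for comparison
with studies that report it.  Range-resolved MARD bins pairs by their
*reference* value into left-closed, right-open 20 mg/dL bins from 40 to
420 mg/dL (the final edge is closed); empty bins carry an explicit NaN, not
0, because 0 would read as perfect accuracy.  Pairing of a CGM trace with
reference points matches each point to the nearest-in-time CGM sample
within a tolerance; an exact tie goes to the earlier sample, which for a
lagging sensor never uses future information.

## Diffusion lag model

The BG-to-IG transfer is the first-order model `tau dIG/dt = -IG + BG`,
`tau = 11 min` by default, solved exactly per step under an assumed
inter-sample behaviour of BG:

* **hold** (default of `simulate_interstitial`): BG constant over each
  interval at its end-of-interval value,
  `IG[n+1] = BG[n+1] + (IG[n] - BG[n+1]) exp(-dt/tau)`.  Exact for step
  inputs and unconditionally stable.  On smooth sampled signals this
  convention effectively advances the input by ~dt/2, so the realized lag
  is `tau - dt/2` (a 23% understatement of the delay effect at tau = 11 on
  a 5-min grid).
* **linear** (default of `delay_only_mard` and `delay_mard_curve`): BG
  piecewise linear between samples (first-order hold), also solved exactly
  per step.  This is the faithful reconstruction of a smooth physiological
  trace: on a 180-min-period sinusoid the discrete solution matches the
  continuous-ODE amplitude to 0.15%.  Dense delay-only MARD therefore uses
  it, avoiding the half-sample bias.

Initial condition `IG(t0) = BG(t0)` avoids a spurious run-in transient.
Both modes agree with an adaptive `solve_ivp` oracle on matching input
assumptions to well below 0.05 mg/dL.

## Reference-measurement error

Reference devices carry zero-mean multiplicative Gaussian error whose 95%
CI half-width is `err_ref` percent, i.e. relative SD `err_ref/100/1.96`.
The perturbed value enters the ARD numerator *and* denominator.  Bias is
deliberately absent: when one meter both calibrates the CGM and supplies
the paired references, a shared bias cancels.  Perturbed values are floored
at 1 mg/dL (logged) because the ARD divides by them.

## Uncertainty surfaces, MRI, ladder

Across Monte Carlo replications, MARD at a design point `(N_ref, err_ref)`
is approximately Gaussian with mean `MARD2 + a*err_ref^2` and SD
`(b + c*err_ref)/sqrt(N_ref)`, with default coefficients
`a = 0.01244 - 0.00037*MARD2`, `b = 51.6178 - 7.7553*MARD2 +
0.3569*MARD2^2`, `c = 0.0037`, valid for MARD2 in [10, 16]% (a warning is
emitted outside).  The `sqrt(N_ref)` denominator follows from the
sample-mean variance scaling and reproduces the measured -0.5 log-log
CI-width slope.  These defaults encode the clinical dataset they were
fitted on; `fit_surface_coefficients` refits `a, b, c` by least squares on
any cohort from a Monte Carlo design grid (mean offsets against
`err_ref^2`; SDs scaled by `sqrt(n)` against `err_ref`), and on synthetic
cohorts the refit surface reproduces independent Monte Carlo moments within
15%.

The MRI solves the erf coverage equation for the symmetric interval around
MARD2 by Brent bracketing on `[0, dMARD + 10 sigma]` followed by Newton
polish; the residual tolerance is 1e-9 in coverage (in practice machine
precision), and the `err_ref = 0` limit equals the exact Gaussian quantile
`1.96 sigma` to ~1e-15 relative.

Subsampling CIs draw subsets *without* replacement (random dropping of
paired points); a bootstrap is available behind `replace=True`, never
default.  All Monte Carlo loops take explicit seeds and are
bit-reproducible.

The idealization ladder evaluates, per replicate of the CGM noise
realization: MARD1 (dense, CGM vs IG truth — delay removed), MARD0 (MARD1
with dense ARDs importance-weighted to the standardized reference
distribution), MARD2 (dense, vs BG truth), MARD3 (the protocol's finite
SMBG schedule, error-free reference) and MARDreal (finite schedule plus
reference error).  Schedule references are the true BG at the matched CGM
sample instant, so a perfect error-free sensor scores exactly zero at every
level and each ladder step isolates one effect.  Note that MARD0 is
conceptually the limiting *expected value*; its Monte Carlo SD reflects
residual CGM-noise variance and is not part of the SD ordering, which is
asserted over MARD1..MARDreal.

## WMARD

Weights `w_i = p_ref(r_i)/p(r_i)`.  The target `p_ref` is a truncated
log-normal (mu = 4.9165, sigma = 0.3832, upper = 450 mg/dL; normalization
`k` = log-normal CDF mass below 450 ~ 0.9991, mode ~ 117.9 mg/dL).  The
study density `p` is a Gaussian-kernel KDE with fixed 10 mg/dL bandwidth,
one equal-weight kernel per point, no boundary reflection or
renormalization: glucose data sit far from 0 relative to the bandwidth, and
weights are ratios in which any global constant cancels.  Reference values
above the truncation get target density 0 and hence weight 0 (the exclusion
count is logged).  A zero estimated density inside the support is an error
— it marks a coverage hole where the ratio is undefined.

Coverage rules are evaluated before weighting: largest gap (including the
distance from each interval edge to the nearest interior point, so a
one-sided cluster cannot pass vacuously) at most 10 mg/dL in [70, 200] and
20 mg/dL in [200, 350]; strictly more than 1% of points (and at least two)
below 70; strictly more than 0.5% (and at least two) above 350.  Failure
raises by default and is overridable with a logged warning.  No weight
capping is applied; extreme weights surface through the effective sample
size `(sum w)^2 / sum w^2`, with a warning below 20% of N.

For Monte Carlo loops the KDE offers a grid-interpolated evaluation path
(linear binning on a 0.25 mg/dL grid, Gaussian convolution, linear
interpolation), accurate to ~1e-4 relative against the exact mixture and
orders of magnitude faster; exact evaluation remains the default for
one-shot computations.

## Synthetic study generator

The generator emulates a 12-subject, 7-day in-patient protocol on a 5-min
grid.  It is descriptive, not a physiological glucose–insulin model: the
metrics only need realistic amplitude and rate-of-change structure, and a
shape-based generator is directly tunable to the statistics that matter.

Per subject: a baseline (uniform 105–130 mg/dL) plus smooth stochastic
drift (Gaussian-filtered white noise, 50-min correlation, 24 mg/dL SD);
three daily meal bumps (double-exponential, rise 20 / decay 70 min,
amplitude 30–60 mg/dL); on excursion days (2 and 5) the meals are
fast-absorbing and insulin-delayed (rise 15 / decay 110 min, amplitude
230–300 mg/dL) and the afternoon/evening meals are followed by deep
insulin-overdose dips with a counterregulatory rebound; non-excursion
nights occasionally carry mild nocturnal dips.  Each trace is affinely
rescaled so the realized mean glucose and mean |dBG/dt| land within 10% of
the targets (150 mg/dL, 0.55 mg/dL/min), clipped to [40, 450], and each
excursion day is guaranteed >=45 min below 70 mg/dL (a dip is carved at the
day minimum if needed).  The targets were chosen so the quasi-steady
approximation `MARD ~ 100 tau E[|dBG/dt|/BG]` lands near 4% at tau = 11;
the realized cohort average is ~3.6%, the shortfall coming from the
correlation between high rates of change and elevated glucose during
meals — within the mean-150/ROC-0.55 envelope, pushing E[|ROC|/BG] higher
would require concentrating variability at low glucose beyond what is
physiological.

The SMBG schedule draws hourly between 06:00 and 22:00 (±10 min jitter)
plus one nocturnal draw per night (01:00–05:00; the final night 23:00–23:55
to stay inside the recording): 126 draws per 7-day subject.  The full study
simulation additionally inserts safety draws every 15 min while the subject
is below 70 mg/dL, as in-patient protocols with induced hypoglycemia
mandate; these also guarantee the hypoglycemic region is represented in the
paired data.  Paired references are the *true* BG at the matched CGM sample
instant — reference error is an analysis-stage injection, not baked into
the data.

The CGM sensor model applies, on top of the diffusion-delayed IG signal:
a sensitivity loss of 1%/day (biofouling) and an extra 10% run-in deviation
decaying linearly over day 1; one-point recalibration every 12 h in which
the sensitivity estimate carries the relative error of the calibration
reference model (default `err_ref` 5%); and 5% multiplicative white display
noise.  The display noise does not feed back into the calibration gain;
calibration error enters only through the calibration error model, keeping
the two error sources separately switchable.

The range-dependent-error cohort used by the WMARD experiments draws 70% of
its reference values from the standardized log-normal and 30% uniformly
over [45, 445] mg/dL, and gives each pair zero-mean Gaussian relative error
whose SD is 5% in euglycemia, twice that below 70 mg/dL and 3 pp higher
deep in hyperglycemia — the qualitative profile reported for real sensors.

## What the synthetic data do and do not show

The generator reproduces the amplitude, rate-of-change, excursion and
sampling structure of an in-patient accuracy study, so passing tests
demonstrate the correctness and calibration of the *metrics and Monte
Carlo machinery* under controlled conditions.  It does not model insulin or
meal pharmacokinetics, inter-sensor correlation, glucose-dependent
reference-meter error profiles, or sensor dropout, so absolute MARD levels
of real devices are outside its scope.  The default uncertainty-surface
coefficients come from a clinical dataset and are not re-derivable from
synthetic cohorts; the refitting path exists for exactly that reason.

## Problem sizes

The test suite uses a 12-subject cohort for the delay analysis, 3000-pair
cohorts with 5000 Monte Carlo replicates for the WMARD invariance
experiment, 1e5 draws for error-model calibration, and a few hundred
replicates per design point elsewhere — sizes at which every asserted
quantity is stable to well within its tolerance while the whole suite runs
in well under a minute of compute per heavy test.
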