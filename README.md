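# cgmard

Accuracy assessment of continuous glucose monitoring (CGM) systems: MARD and
range-resolved MARD, the distribution-corrected WMARD, the MARD reliability
index (MRI), Monte Carlo uncertainty analysis over the number and accuracy of
reference measurements, the blood-to-interstitial glucose diffusion lag
model, and a synthetic in-patient study generator so every procedure is
testable without clinical data.

## The problem

CGM sensors are evaluated in clinical trials by comparing their readings
`y_CGM(t_k)` with paired reference blood-glucose (BG) point measurements
`y_ref(t_k)` (finger-prick SMBG or laboratory analyzers).  The dominant
accuracy metric is the mean absolute relative difference:

```
ARD_k = 100% * |y_CGM(t_k) - y_ref(t_k)| / y_ref(t_k)
MARD  = (1/N_ref) * sum_k ARD_k
```

A reported MARD, however, reflects more than sensor quality.  It is inflated
and blurred by

* the **physiological lag** between blood and interstitial glucose (IG),
  described by the two-compartment diffusion model
  `tau * dIG/dt = -IG + BG` with `tau ~ 11 min` — even a perfect IG sensor
  shows a nonzero MARD against BG whenever glucose is changing;
* the **reference device's own error**, modelled as multiplicative Gaussian
  noise with 95%-CI half-width `err_ref` (so SD = `err_ref/1.96`), which
  adds `dMARD = a * err_ref^2` to the expected MARD;
* the **finite number of paired points** `N_ref`, which makes MARD a random
  variable with SD `sigma_MARD = (b + c*err_ref)/sqrt(N_ref)`;
* the **glycemic distribution of the paired points**: sensors are least
  accurate in hypoglycemia, so a study rich in low reference values reports
  a higher MARD for the same device.

This package implements the correction and uncertainty tools for all four
effects.  The **MRI** is the half-width of the symmetric interval around the
idealized `MARD2` containing 95% of the MARD sampling distribution, obtained
by solving

```
0.95 = 1/2 * [ erf((MRI - dMARD)/(sqrt(2) sigma)) - erf((-MRI - dMARD)/(sqrt(2) sigma)) ]
```

The **WMARD** reweights each ARD by `w_i = p_ref(r_i) / p(r_i)`, where
`p_ref` is a standardized truncated log-normal reference distribution
(log-location 4.9165, log-scale 0.3832, truncated at 450 mg/dL) and `p` is
the study's own reference-value density estimated with a Gaussian KDE of
fixed 10 mg/dL bandwidth, making MARD values comparable across studies with
different glycemic designs.  Coverage rules (maximum data gaps of 10 mg/dL
in 70–200 and 20 mg/dL in 200–350; >1% of points below 70; >0.5% above 350)
guard against reweighting into regions without data.

## Worked example

Simulate a 12-subject, 7-day in-patient study (5-min CGM grid, hourly
daytime SMBG plus nocturnal and hypo-safety draws, glucose excursion days 2
and 5) and evaluate it:

```python
import numpy as np
from cgmard import (DelayModel, compute_mard, compute_mri, compute_wmard,
                    delay_only_mard, simulate_study, subsample_mard_ci)
from cgmard.metrics import concatenate

scenario, cgms, paired = simulate_study(seed=1)
pooled = concatenate(paired)

est = compute_mard(pooled)
res = compute_wmard(pooled)
delay = np.mean([delay_only_mard(bg, DelayModel(11.0))
                 for bg in scenario.bg_traces])
mri = compute_mri(n_ref=pooled.n, err_ref=5.0, mard2=12.0)
ci = subsample_mard_ci(pooled, n_ref=200, reps=2000, seed=1)
```

This prints (with the formatting of the example script):

```
MARD  : 5.95%  (N = 1654 paired points)
WMARD : 6.30%  (ESS = 1207, coverage passed = True)
delay-only MARD at tau=11: 3.61% (cohort mean)
MRI(nref=1654, err_ref=5%, MARD2=12%): 0.60 pp
MARD 95% CI at nref=200: [5.33, 6.65]
```

Reading the numbers: the simulated sensor's study MARD is 5.95%, of which
~3.6 pp would be present even for a *perfect* IG sensor, purely from the
11-min diffusion lag.  WMARD standardizes the value to the reference
glycemic distribution (slightly higher here because the study over-samples
the well-behaved euglycemic range relative to the target).  A study of this
size run with a 5%-error reference meter pins a MARD2 = 12% device down to
±0.60 pp; cutting the study to 200 paired points widens the subsampling CI
to about ±0.7 pp.

A command-line interface mirrors the library:

```
cgmard simulate-study --subjects 12 --days 7 --seed 1 -o study/
cgmard mard study/subject00_paired.csv --by-range
cgmard wmard study/subject00_paired.csv --force
cgmard mri --nref 200 --err-ref 5 --mard2 12
cgmard mc-uncertainty study/subject00_paired.csv --nref 100 --err-ref 5 --reps 5000 --seed 1
```

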