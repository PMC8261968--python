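# paspectrum

Multivariate pattern analysis of children's accelerometer-measured physical
activity against metabolic-syndrome risk factors.

Traditional accelerometry collapses a week of 30 Hz tri-axial data into a
handful of cut-point variables (sedentary, light, moderate, vigorous
minutes), discarding most of the intensity information and blurring exactly
the vigorous range where health associations concentrate. `paspectrum`
implements the alternative end to end:

1. **Signal processing** — band-pass filter each axis with a wide
   ("frequency-extended", default 0.29–10 Hz Butterworth, zero-phase) filter
   that preserves the 2.5–3 Hz step frequencies of running children, combine
   axes into a vector magnitude, and average into 3-second epochs; zero the
   23:00–06:00 night window, detect non-wear (≥ 60 min of zero output with a
   cumulative 2-min sub-light-intensity allowance), and keep subjects with
   ≥ 4 days of ≥ 10 h wear.
2. **Intensity spectrum** — partition wear time into 22 narrow bins
   (edges 0, 40, 80, 160, 240, …, 1600 mg and above), minutes/day per bin,
   plus the traditional cut-point summary for comparison, with
   standardized group mean profiles and 10⁴-rep bootstrap CIs.
3. **Risk factors** — HOMA-IR from fasting glucose and insulin, age- and
   sex-stratified z-scores (blood pressure additionally height-adjusted),
   and the composite MetS score
   `z_waist + z_IR + (z_SBP + z_DBP)/2 + (z_TG − z_HDL)/2`.
4. **PLS multivariate pattern analysis** — the 22 bins are far too collinear
   for ordinary regression, so outcomes are modelled by PLS1 regression
   (SIMPLS): Monte-Carlo cross-validated R² (1000 repetitions), complexity
   selection by a backwards half-SD rule, permutation tests (10⁴ reps),
   target projection of the components onto the single predictive direction
   w ∝ b, and the **selectivity ratio** — each predictor's signed explained
   variance of the response — with percentile-bootstrap CIs. A four-model
   confounder strategy (activity + confounders / activity only / confounders
   only / activity vs confounder-residualized response) yields the
   model-strength table.
5. **Synthetic cohort generator** — the original cohort data are not
   publicly available, so a generator produces raw signals (sinusoidal
   activity bursts on gravity), epoch series (Poisson bouts, exponential
   durations, gamma intensities), confounders and outcomes with known effect
   vectors and true R², making every stage testable and enabling
   parameter-recovery experiments.

## Worked example

```python
import numpy as np
from paspectrum import (CohortConfig, generate_spectrum_cohort,
                        generate_outcomes, noise_sd_for_r2,
                        standardize_spectrum, PLS)

cfg = CohortConfig(n_subjects=1000, seed=7)
spectrum_min, confounders = generate_spectrum_cohort(cfg)   # minutes/day, 22 bins
z = standardize_spectrum(spectrum_min)

beta = np.zeros(22); beta[9:14] = -1.0          # adverse effect, bins 10-14
sd = noise_sd_for_r2(z.to_numpy(), beta, 0.10)  # true R^2 = 0.10
y, truth = generate_outcomes(
    z.to_numpy(), None,
    CohortConfig(n_subjects=1000, beta_spectrum=tuple(beta), noise_sd=sd, seed=7))

res = PLS(y, z).fit(a_max=6, cv_reps=200, seed=7)
print(res.summary())
sr = res.selectivity_ratio(overall="cv")
print("SR peak at bin index", sr.peak_index, "value %.3f" % sr.peak_value)
```

prints

```
PLS regression results
======================
n obs                1000
n predictors         22
n components (A)     1
training R^2         0.1036
cross-validated R^2  0.0979
CV repetitions       200
largest |coefficients| (standardized):
  960-1040             -0.0206
  880-960              -0.0206
  1040-1120            -0.0205
  800-880              -0.0204
  1120-1200            -0.0204
SR peak at bin index 12 value -0.096
```

The model recovers the planted effect: the cross-validated explained
variance (9.8%) sits near the true 10%, the largest standardized
coefficients sit in the 800–1200 mg bins around where the effect was
planted, and the selectivity-ratio peak (bin index 12 = 880–960 mg, signed
negative) says that time at vigorous intensity carries the strongest share
of the response's explained variance.

A full pipeline — epoch files + cohort table in, tables/figures/manifest
out — runs from a YAML config:

```bash
paspectrum simulate --outdir demo --seed 1 --n-subjects 300
paspectrum all --config examples/demo_config.yaml
```

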