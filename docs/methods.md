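# Methods

This note records the models, conventions and numerical choices behind
`paspectrum`, and what the synthetic-data experiments do and do not show.

## Signal processing

Raw tri-axial acceleration (30 Hz, ±6 g) is band-pass filtered per axis and
combined into a vector magnitude. The default filter is a 4th-order
Butterworth band-pass with half-power edges at 0.29 and 10 Hz, applied
forward-backward (`scipy.signal.sosfiltfilt`) for zero phase; the effective
amplitude response is therefore the squared magnitude of the one-pass
design. The wide upper edge is the point: children's step frequency during
vigorous activity is roughly 2.5–3 Hz, and narrow (~1.66 Hz) activity-count
filters attenuate precisely the content that separates moderate from
vigorous intensity. The exact coefficients of published frequency-extended
filters are not reproduced here; the band edges, order and design are
configurable, and the filter tests compare measured sinusoid gain against
the filter's own analytic response (`sosfreqz`), not against any external
coefficient set.

Filtered vector magnitude is averaged into 3-s epochs (90 samples; trailing
partial epochs discarded, so epoching conserves the sample sum over complete
epochs). Conventions:

* **Night window** [23:00, 06:00), half-open on epoch start time, is forced
  to zero and excluded from wear time. Without the exclusion, the seven
  guaranteed-zero night hours would register as non-wear and distort daytime
  sedentary totals.
* **Zero output** means vm < 1 mg (sensor-noise floor after filtering);
  configurable.
* **Non-wear**: a span is off-body when it starts and ends on zero epochs,
  lasts ≥ 60 min, contains no epoch at or above the light-intensity cut, and
  its sub-cut interruptions total ≤ 2 min. The allowance is cumulative
  across the span (the convention is ambiguous in the field; both the greedy
  detector and the exhaustive test oracle implement the cumulative reading,
  and the choice is exposed as parameters). Only the first zero epoch of a
  zero-run can start a maximal span, which is what makes the linear-time
  detector equivalent to the exhaustive span-by-span oracle.
* **Validity**: a day is valid at ≥ 600 wear minutes, a measurement at ≥ 4
  valid days; thresholds are strict (599.95 min fails).

## Intensity spectrum

Wear epochs of valid days are histogrammed into 22 half-open bins with edges
0, 40, 80, 160, 240, then +80 mg per bin to 1600 mg, plus an open top bin
(≥ 1600 mg); minutes/day are averaged over valid days only, so the bins
partition mean daily wear time exactly. Default cut-points for the
traditional summary are 40 / 360 / 710 / 1065 mg for the 1.5 / 3 / 6 / 9 MET
boundaries — the interior values interpolate on a MET-linear acceleration
scale between the sedentary cut and the vigorous range implied by the top
spectrum edge sitting ~50% above the very-vigorous cut; all four are
configurable since published calibration values vary by filter chain.

Bins are z-scored across subjects (sample SD, ddof = 1); zero-variance bins
are dropped with a warning. Group mean profiles carry 95% percentile
bootstrap CIs from resampling subjects within group (default 10⁴
resamples). Standardization is global (not within-group), so a single
all-sample group has mean exactly zero in every bin.

## Risk factors and MetS score

HOMA-IR = glucose [mg/dl] × insulin [µU/ml] / 405 (the mass-unit HOMA1
constant, matching the panel's units). Risk factors are standardized within
age-band × sex strata (2-year bands, bands merged upward until each stratum
holds ≥ 10 subjects); blood pressure is first residualized on height within
stratum. This internal-sample standardization replaces external paediatric
reference tables, which are not redistributable — z-scores therefore have
mean 0 / SD 1 within this sample rather than relative to a reference
population, which changes the interpretation of individual scores but not
the structure of downstream associations. The composite score,

    MetS = z_waist + z_IR + (z_SBP + z_DBP)/2 + (z_TG − z_HDL)/2,

weights adiposity, insulin resistance, blood pressure and lipids equally;
HDL enters reversed; any missing component leaves the score missing.

## PLS multivariate pattern analysis

Predictors and response are z-scored before fitting. The fitting algorithm
is SIMPLS for a single response: components maximize covariance with the
response under orthonormal scores, and the regression vector truncated to
any number of components is available from one pass. At one predictor the
coefficient equals the Pearson correlation; at full rank the predictions
equal ordinary least squares — both serve as oracles in the tests, along
with an independent NIPALS implementation (scikit-learn) for the
multi-component case.

**Cross-validation.** Model strength is Q² = 1 − PRESS/TSS from Monte-Carlo
resampling: per repetition a random 20% holdout is predicted by a model
(including all standardization) re-estimated on the remaining 80%, and
errors are pooled over repetitions (default 1000). TSS is taken against the
training-mean prediction. Note that under a pure-noise null this statistic
is slightly negative in expectation (≈ −p/n_train at one component, since
the first component always absorbs some noise covariance); tests assert a
band around that actual null behaviour rather than around zero.

**Complexity selection.** All candidate complexities 1..A_max are scored on
shared splits (one SIMPLS pass per split at A_max gives every truncation).
From the minimum-mean-error complexity, the rule steps backwards while the
simpler model's mean holdout MSE stays within 0.5 across-repetition SDs of
the minimum (the SD of the minimum model's per-repetition errors), returning
the smallest such complexity. The SD convention is one of several
operationalizations of the half-SD rule; this one is paired (shared splits)
and errs toward parsimony.

**Permutation test.** The response is permuted n_perm times (default 10⁴)
and the cross-validated R² recomputed per permutation with a reduced inner
repetition count, on splits shared across permutations;
p = (1 + #{null ≥ observed}) / (1 + n_perm). Complexity is *not* re-selected
per permutation (fixed at the observed selection) — re-selection at 10⁴
permutations is computationally implausible and the approximation is mildly
anti-conservative; empirical size at the 5% level is checked by simulation
(400 null datasets) in the acceptance suite.

**Target projection and selectivity ratio.** The fitted components collapse
onto w_TP = b/‖b‖, t_TP = X·w_TP, p_TP = Xᵀt_TP/(t_TPᵀt_TP). Predictor j's
selectivity ratio is sign(b_j) · [(t_TPᵀt_TP)·p_TP,j² / ‖x_j‖²] · R²_overall
— its signed specific explained variance of the response. R²_overall
defaults to the model's cross-validated R² (clipped at 0), configurable to
training R²; by Cauchy–Schwarz |SR_j| ≤ R²_overall always.

**Bootstrap CIs.** Subjects are resampled with replacement (default 10⁴),
the PLS model refitted at fixed complexity on each re-standardized resample,
and percentile 2.5/97.5 bounds taken per predictor. The overall-R² factor is
held at its point estimate inside the bootstrap: re-running the full
Monte-Carlo CV inside every resample would multiply cost by the CV
repetition count for a scalar that shifts all bins equally, so the CIs
propagate uncertainty in the variance-ratio profile and the coefficient
signs, not in the overall scale. Resamples with a zero-variance predictor
are redrawn and logged.

**Confounder strategy.** Age (standardized), sex, country, household income
and parental education (one-hot minus first-observed reference level) form
the confounder design. Four models per response: spectrum + confounders,
spectrum only, confounders only, and spectrum against the response
residualized on the confounders (OLS with intercept, residuals re-z-scored
so strengths stay comparable). Because PLS components mix predictor
variance, the first three models bracket the shared association; the fourth
ascribes all shared variance to the confounders and isolates the net
activity association. Age and sex stay in the design even for z-scored
responses since the analysed subsample need not match the standardization
sample. Complete cases are selected per response, not globally.

## Synthetic cohort generator

The generator supplies the study conditions for every simulation-based
test; its defaults emulate a child cohort wearing hip accelerometers for a
7-day week:

* **Bout process**: homogeneous Poisson bout arrivals (10/h) within a
  06:00–23:00 wake window, exponential durations (mean 100 s), gamma bout
  intensities (shape 1.8, mean 250 mg); between bouts, gamma rest epochs
  (shape 1.5, mean 18 mg, mostly below the 40 mg sedentary cut). These
  values put the default subject near the published cohort's composition
  (roughly 680–700 sedentary, ~200 light and ~90–110 moderate-to-vigorous
  minutes/day) without copying any subject-level data.
* **Heterogeneity**: per-subject lognormal multipliers on bout rate
  (σ = 0.30) and intensity (σ = 0.22) create the between-subject spectrum
  variance and the strong neighbouring-bin correlations the real spectrum
  exhibits; group shifts add mg offsets to mean bout intensity.
* **Raw signal synthesis**: bouts are sinusoids at the profile's step
  frequency (default 2.8 Hz, constrained to 2.0–3.5 Hz) riding on 1 g
  gravity, full amplitude on the vertical axis and 20% on the other two,
  clipped to ±6 g. The amplitude maps the drawn intensity through the
  rectified-sine mean so epoch vector magnitudes land near the target. This
  exercises filter gain and epoching; it is not a biomechanical gait model,
  so nothing downstream should be read as validating cut-points against
  real locomotion.
* **Fast spectrum-level path**: for 1000-subject recovery experiments the
  same mechanism is sampled per bin (Poisson/binomial bout epoch counts,
  multinomial over the gamma-implied bin probabilities) instead of per
  epoch.
* **Outcomes**: y = Z·β_spectrum + D·β_confounders + N(0, σ²), with the
  realized variance decomposition and implied true R² recorded;
  `noise_sd_for_r2` inverts the relation for a target R².
* **Complexity ground truth**: `generate_latent_rank_data` builds predictors
  from k orthogonal latent scores with flat-magnitude sign-pattern loadings
  (uniform, alternating, …) and staggered scales. Flat loadings make every
  predictor's variance equal, so the per-column standardization inside
  cross-validation rescales uniformly and cannot collapse the scale
  staggering — which is exactly what keeps one covariance direction from
  absorbing the whole signal and makes "needs exactly k components"
  well-defined and testable.

What passing these tests shows: the pipeline recovers planted effect
locations, strengths and complexities under a realistic intermittent-
activity correlation structure, and its inference is calibrated under the
null. What it does not show: performance on real gait signals, real
measurement artifacts (device swaps, idle-sleep modes), or real confounder
distributions.

## Problem sizes and runtime choices

Defaults follow full-scale inference (1000 CV repetitions, 10⁴ permutations,
10⁴ bootstrap resamples). The test and acceptance runs scale down, as their
own condition choices: recovery experiments use n = 1000 subjects × 20
replicate seeds with 100 CV repetitions; permutation calibration uses 400
null datasets of n = 100 with 200 permutations × 25 inner repetitions;
bootstrap coverage uses 30 datasets × 2000 resamples; the demo pipeline uses
n = 300 subjects with 200 CV / 500 permutation / 1000 bootstrap repetitions.

## Known limitations

* The filter approximates the frequency-extended family by band edges and
  order, not by published coefficient sets; absolute epoch magnitudes are
  therefore not comparable to outputs of any specific proprietary chain.
* Cut-point defaults interpolate on a MET-linear acceleration scale;
  studies calibrating against indirect calorimetry report somewhat
  different values.
* Internal-sample z-scores are not reference-population z-scores.
* The permutation statistic fixes model complexity at the observed
  selection; the selectivity-ratio bootstrap fixes the overall-R² scale.
* Single-response PLS1 only; no multi-response, sparse or orthogonalized
  variants.
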