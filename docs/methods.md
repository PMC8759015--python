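# Methods

## Data model and segmentation

Input streams are per-subject timestamped HR samples (`hr_bpm`) and sleep
*state-change* events (`awake`/`light`/`deep`); the watch stores only
changes, so nightly sleep intervals must be reconstructed. All timestamps
live in one study timezone (naive, no DST handling). Study days are indexed
relative to the first dosing day (day 0) through a per-subject
`anchor_date` in the allocation table.

The night of study day *d* is searched in the half-open window
[noon of *d*, noon of *d*+1) and attributed to *d*, the evening on which
sleep begins. Its interval runs from the first non-awake state change to
the last state change of the window — the literal reading of "first sleep
state until the last state change of the following day" when mornings
contain several transitions. Three statuses result:

* `detected` — interval ≥ 3 h; its HR samples form the asleep series;
* `excluded_short` — interval < 3 h; the asleep series is dropped, but the
  interval still bounds the neighbouring awake periods (only the asleep
  *series* is excluded, not the day);
* `missing` — no non-awake event in the window.

The awake period of day *d* is everything strictly between the previous
night's end and night *d*'s start. The asleep interval is closed and awake
windows are open at sleep boundaries, so a sample exactly on a boundary is
asleep — a deterministic tie-break. When a bounding night is `missing` the
corresponding bound falls back to a fixed clock window, 9 AM (inclusive) to
9 PM (exclusive), and the day is flagged `default_window`.

Each non-empty subject-day-period series is summarized by its 2.5th, 50th
and 97.5th percentiles using linear interpolation between closest ranks
(index h = (n−1)p, the default of mainstream numeric stacks). No minimum
sample count is imposed beyond non-emptiness; `n_samples` is recorded so
users can filter. Percentile conventions differ only at tiny n and do not
move the variance-component conclusions.

## Statistical models

Every model is a Gaussian linear mixed model with a per-subject random
intercept, fitted by REML:

* **Repeatability** (per marker, predose days −6..−1):
  `value ~ 1 + day`, day categorical with 6 levels. The predose window is
  −6..−1: the day factor must carry 5 numerator df, which a window ending
  at day 0 would not.
* **Treatment** (per marker, days −6..6) and **sleep duration** (detected
  nights only): `value ~ 1 + day * arm`, day 13 levels, arm 2 levels.

Derived quantities:

* **ICC** = σ²_b / (σ²_b + σ²_w), clamped to [0, 1]; negative
  variance-component estimates are truncated at the boundary (λ = 0 REML),
  the standard convention that keeps the ICC interpretable.
* **Type III F tests** from the joint Wald statistic of each sum-to-zero
  coded term, with between-within (containment) denominator df: terms
  varying within subjects are tested against N − n_subjects − p_within;
  between-subject terms against n_subjects − rank(between design). On
  balanced complete data this gives 55 (repeatability day test) and
  120 / 10 / 120 (treatment day / arm / interaction). Kenward–Roger df,
  which some mixed-model stacks use, differ on unbalanced data and can move
  p-values in the second decimal; no conclusion here depends on the df
  method.
* **Baseline contrasts**: for each arm and dosing day d, weight +1 on day
  d's estimated marginal mean and −1/6 on each predose day's, within arm.
  Two-sided t reference at the within-subject containment df; Bonferroni
  family = 14 (7 dosing days × 2 arms) per marker model. The reporting
  layer additionally caps displayed adjusted p-values at .99
  (`p_display`); the exact min(1, 14·p) is kept in `p_adj`.
* **MDE** (inverse sample-size calculation):
  MDE = (t₁₋α/2,n−1 + t_power,n−1) · σ_total · √(2/n), with
  σ_total = √(σ²_b + σ²_w) from the repeatability fit, α = .05,
  power = .80, n = 12. The √(2/n) two-sample difference form matches a
  parallel-group comparison; a paired form (√(1/n)) is available via
  `mde_form: paired`. The relative MDE (`mde_pct`) is defined against the
  model-estimated marker mean (the sum-coded intercept); reference tables
  computed from other mean definitions can differ by a few tenths of a
  percentage point.
* **Cohen's d** = contrast / √(σ²_b + σ²_w), using the variance components
  of the treatment model itself. Note that standardizing by an *estimated*
  SD at n = 12 subjects inflates the mean of d̂ by ≈ 3–4 % (Jensen's
  inequality on 1/√σ̂²); replicate studies of a 16.18 bpm shift over total
  variance 34.64 therefore average ≈ 2.85 rather than the generating 2.75.

### REML implementation

Because the random structure is a single intercept, the REML criterion is
profiled to one dimension, the variance ratio λ = σ²_b/σ²_w. Per-subject
blocks give V_i⁻¹ = I − λ/(1+λn_i)·J by the Woodbury identity, so the
criterion and its analytic gradient (the residual term via the envelope
theorem) reduce to cached cross-products; the optimum is located by bounded
scalar minimization followed by a Brent root-find on the gradient
(xtol 1e−14). On balanced data the estimates agree with the closed-form
ANOVA method-of-moments (σ̂²_w = MSW, σ̂²_b = (MSB−MSW)/k) to ~1e−11, and
with statsmodels `MixedLM` to ~1e−6 on unbalanced data (MixedLM serves as
an independent cross-check in the test suite). Exactly noiseless inputs
(residual variance numerically zero) have no interior REML optimum; they
are detected and solved exactly by least squares with sum-to-zero subject
dummies, returning zero variance components and exact fixed effects.
Non-converged fits are flagged and refused by all downstream operations.

## Synthetic cohort generator

The generator emulates the trial design: 12 subjects, placebo:active 1:2
(4/8), days −6..6, active-arm dose titrated 20 → 40 → 80 µg over days
0–2. Each HR sample is

    hr(t) = μ_period + b_i + ε_{i,day,period} + circadian(t)
            + effect(day, period)·[active] + burst(t) + noise,

with b_i ~ N(0, σ²_b) (default σ_b = 4.9 bpm), a day-level cell deviation
ε ~ N(0, σ²_w) (σ_w = 3.3 bpm) shared by all samples of one
subject-day-period, per-sample noise N(0, 6²), and a single-sinusoid
circadian term (amplitude 3 bpm, peak at 15:00) — the minimal smooth daily
profile. Period means default to 63.2 (asleep) and 75.4 bpm (awake), the
published predose medians; the default `effect_profile_bpm` follows the
published active-arm post-hoc contrasts per day and period (asleep onset on
the first treatment night, plateau at the 80 µg dose). Samples are clipped
to the device-plausible 25–240 bpm.

Nights start around 23:30 (SD 45 min) and last
N(6.5 + subject offset, 0.6²) h, where the subject offset has SD 0.8 h —
the between/within split that reproduces the published sleep-duration
repeatability (0.64 = 0.8²/(0.8²+0.6²)). Sleep events alternate
light/deep roughly every 90 min and end with a terminal awake transition,
so generated event streams are valid change-point sequences. A night emits
no events at all with probability 0.1 (unrecorded sleep states) and is
truncated below 3 h with probability 0.02, matching the observed
missingness modes. A lead-in night before the first study day gives day −6
a proper morning boundary.

Sampling runs on a 10-min grid (random phase per day) with one daytime
activity burst per day at 1-min cadence; the default burst length of
12 min calibrates the mean awake count: 17.5 h awake × 6/h ≈ 105 base
samples plus the burst's net ≈ +11 gives ≈ 116 awake and 6.5 h × 6/h ≈ 39
asleep samples per patient-day, the published availability. Burst samples
carry a +28 bpm exercise elevation, which produces a realistic Awake-High
tail. How the real device triggers and paces activity oversampling is not
public; the burst model is a stand-in, not a device emulation.

`simulate_marker_table` generates directly at the level the mixed models
consume (value = μ + fixed(day, arm) + b_i + ε_id), which is what the
replicate recovery studies use: it isolates the statistical stage from
segmentation and runs two orders of magnitude faster.

**What passing recovery tests do and do not show.** The generator shares
the Gaussian random-intercept structure of the analysis models, so
recovery studies are well-posed checks of the estimators — not evidence
about real PPG data, which bring motion artefacts, wear-time gaps,
device-side filtering and non-Gaussian tails that are deliberately out of
scope (no PPG waveform, accelerometry or battery modeling). Stream-level
simulations add circadian structure and percentile sampling noise beyond
σ²_w, so stream-derived ICCs sit slightly below the marker-level
generating ICC; single-cohort ICC estimates at n = 12 additionally carry a
standard error near 0.1.

## Replicate studies and problem sizes

The recovery studies (`pulsewatch.studies`) run the full statistics
pipeline on replicate synthetic studies at trial scale (12 subjects; 6
predose days for repeatability, 13 days for treatment models): 200
replicates for mean-ICC and mean-d recovery, 500 for the family-wise error
rate of the Bonferroni-corrected contrast family, and ≥1000 simulated
patient-days (7 default cohorts) for the sampling-calibration counts.
Replicate seeds are spawned from a single root seed, so every study is
exactly reproducible. The family-wise error rate of the implementation,
measured once at high precision (3000 replicates), is 0.043 ± 0.004 —
comfortably inside the Bonferroni guarantee; a 500-replicate draw of this
rate has binomial SD ≈ 0.009, which the test suite accounts for with an
exact one-sided binomial test.

## Known limitations

* One sleep interval per noon-to-noon window: naps are not modelled and
  would be absorbed into the awake period.
* Containment df, not Kenward–Roger: second-decimal p-value differences on
  unbalanced data are expected against nlme/lme4+pbkrtest output.
* The ICC ratio estimator and Cohen's d are small-sample biased (downward
  ≈ 0.02 and upward ≈ 3–4 % respectively at 12 subjects); the package
  reports the conventional estimators and quantifies the bias in its
  replicate studies rather than correcting it.
* No bootstrap or profile confidence intervals for ICC/MDE.
* HR variability indices and light-vs-deep substate analyses are out of
  scope.
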