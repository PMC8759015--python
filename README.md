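# pulsewatch

Repeatability and treatment-sensitivity analysis of smartwatch heart-rate
biomarkers, with a sleep-aware segmentation pipeline and a synthetic cohort
generator.

Consumer wrist wearables estimate heart rate (HR) from photoplethysmography
every ~10 minutes and store sleep as state-change events (awake / light /
deep). In early-phase clinical trials such streams can serve as at-home
digital biomarkers — if their repeatability and sensitivity are adequate.
`pulsewatch` implements that evaluation for a parallel-group design
(baseline days −6..−1, dosing days 0..6, placebo:active 1:2): it

1. reconstructs nightly sleep intervals from the state-change events
   (first non-awake change → last change of the noon-to-noon window;
   asleep series < 3 h and nights without sleep states are excluded),
2. splits each day's HR samples into **asleep** and **awake** periods
   (falling back to a 9 AM–9 PM window when sleep states are missing),
3. summarizes each subject-day-period series by its 2.5th, 50th and 97.5th
   percentiles — the six markers Awake/Asleep-Low/Median/High,
4. fits per-marker random-intercept linear mixed models (REML) and reports:
   - **ICC** = σ²_b / (σ²_b + σ²_w), the between-subject share of the total
     variance (repeatability),
   - **MDE** = (t₁₋α/2,n−1 + t_power,n−1) · σ_total · √(2/n), the minimum
     detectable effect of an inverse sample-size calculation (α=.05,
     power=.80, n=12 by default),
   - type III F tests for day, treatment and day × treatment,
   - per-dosing-day contrasts against the averaged predose level with
     Bonferroni correction (family = 7 days × 2 arms), and
   - **Cohen's d** = contrast / √(σ²_b + σ²_w).

Because trial device data are not public, the package ships a calibrated
generator (`pulsewatch.synthetic`) producing HR sample streams, sleep-event
streams, allocation tables and ground truth with known parameters: ~10-min
sampling with daily activity bursts, a sinusoidal circadian profile,
between-/within-subject variance components, a dose-titrated active-arm
effect profile, and realistic missingness (unrecorded sleep states, short
nights). Every statistical claim is validated by replicate recovery studies
against this ground truth.

## Worked example

```sh
pulsewatch simulate --out demo/data --seed 11
pulsewatch run --hr demo/data/hr.csv --sleep demo/data/sleep.csv \
    --allocation demo/data/allocation.csv --out demo/report
```

The simulated cohort (12 subjects × 13 days) yields 26,011 HR samples and
877 sleep events; the run log accounts for every night:

```
nights: 144 detected, 9 missing sleep states, 3 shorter than 3 h
marker rows: 900
```

`repeatability.csv` holds the predose summary per marker — estimated mean
(bpm), ICC, MDE and the day F test:

```
period,marker,mean_bpm,se,icc,mde_bpm,mde_pct,f_day,df_num,df_den,p_day
asleep,median,61.1005,1.0925,0.407268,6.60889,10.8164,0.751376,5,49,0.589104
...
```

(with 12 subjects, a single cohort's ICC estimate carries a standard error
of roughly 0.1 — the replicate studies below quantify this). The contrast
table shows the injected active-arm effect emerging over the dose
titration; e.g. the asleep-median marker (estimate ± SE in bpm, Bonferroni
p):

```
period,marker,arm,day,estimate_bpm,se_bpm,df,p_raw,p_adj,...
asleep,median,active,0,3.36008,1.51783,108,0.0289488,0.405284,...
asleep,median,active,1,8.19627,1.51783,108,3.99478e-07,5.59269e-06,...
asleep,median,active,3,16.0445,1.51783,108,2.34023e-18,3.27632e-17,...
```

and `sleep_model.csv` confirms sleep duration itself is unaffected
(day × treatment F₁₂,₁₀₈ = 0.57, p = .87; ICC = 0.63).

Replicate recovery studies (estimates vs generating truth) run with:

```sh
pulsewatch recover --replicates 200
```

## Layout

| module | role |
| --- | --- |
| `pulsewatch.synthetic` | cohort/stream/marker-table generators + ground truth |
| `pulsewatch.ingest` | CSV readers, night reconstruction, day segmentation |
| `pulsewatch.markers` | percentile markers and the long marker table |
| `pulsewatch.lmm` | profiled-REML random-intercept fits, type III F tests |
| `pulsewatch.repeatability` | ICC, day F test, MDE |
| `pulsewatch.treatment` | day × arm models, baseline contrasts, Cohen's d |
| `pulsewatch.pipeline` / `cli` | orchestration, report tables, CLI |
| `pulsewatch.studies` | replicate parameter-recovery studies |

See `docs/methods.md` for the statistical model, generator assumptions and
numerical choices.
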