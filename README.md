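# ccmpipe

Analysis pipeline for chronic circadian misalignment (CCM) experiments in
*Drosophila*: beam-break activity data from Drosophila Activity Monitors
(DAM), sleep and rest:activity rhythm analysis, lifespan modelling, and
cross-classification of misalignment- versus aging-driven gene expression
changes.

## The problem

Forcing an animal's ~24-h internal clock to track a non-24-h world — here,
an LD14:14 schedule whose 28-h "days" impose a 4-h phase delay every cycle —
shortens lifespan. Quantifying that effect from DAM data requires a chain of
inferences, each with its own pitfalls:

* **Death calling.** A DAM only sees beam breaks; lifespan is the last
  minute with a count. Sensor "ghosts" — single isolated counts appearing
  long after the fly's real activity has ceased — would inflate lifespan, so
  any nonzero bin more than 12 h away from all other activity (on both
  sides) is removed first.
* **Sleep.** Fly sleep is behaviorally defined as ≥ 5 consecutive minutes
  without a beam break. Weekly summaries (min sleep/hr over 168 h) include
  only flies that survived the whole week; full-life summaries drop the
  last three days, when moribund stillness mimics sleep.
* **Rhythmicity.** The chi-squared periodogram (Sokolove–Bushell) folds the
  1-min series at each trial period P and scores the between-column
  variance: Q(P) = N·Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)².  Rhythm power is
  Q at the dominant period minus the χ²(P−1) significance line at α = 0.01.
  Free-running (DD) analyses exclude the first day after transfer to
  darkness.
* **Survival modelling.** Kaplan–Meier curves with 95% CIs, the log-rank
  test, and Cox proportional-hazards models (Efron ties), including the
  multivariate treatment + sleep model and a sleep-matched cohort (each
  control fly greedily paired with a CCM fly within 0.5 min/hr of sleep) to
  separate the misalignment effect from its modest sleep cost.
* **Expression cross-classification.** Given two DESeq2 result tables —
  CCM vs control, and aging (control week 3 vs week 2) — each CCM-significant
  gene (FDR < 0.1) is classed as `convergent` (same direction, aging FDR
  < 0.1), `trend_same` (same direction, FDR ∈ [0.1, 0.3)), or `opposite`
  (opposite direction, FDR < 0.3); `opposite` genes are candidate direct
  consequences of misalignment rather than accelerated aging.

Because raw DAM data of this kind are rarely deposited, the package ships a
ground-truth simulator (`ccmpipe.synthetic`): a two-state active/rest Markov
chain shaped by the light schedule (night rest, midday siesta, anticipation
ramps, clock-driven morning/evening peaks that free-run in DD), Gompertz
mortality with a programmable treatment hazard ratio, and post-mortem ghost
counts. Every pipeline stage is tested by recovering what the simulator
programmed.

## Worked example

```python
from ccmpipe.pipeline import default_config, run_pipeline

cfg = default_config()
cfg["seed"] = 1
cfg["simulate"] = {"n_per_group": 30, "horizon_days": 40.0, "sex": "male", "params": {}}
cfg["analysis"] = {"weeks": [1], "rhythm_flies_per_arm": 8, "sleep_match_tolerance": 0.5}
report = run_pipeline(cfg)
```

Selected fields of the resulting report:

```
survival.control_median_days        23.63
survival.ccm_median_days            17.84
survival.percent_median_reduction   24.5
survival.logrank_p                  0.0199
hazard_models.ccm_univariate        HR 1.91 (95% CI 1.10–3.34)
hazard_models.sleep_univariate      HR 0.64 per extra hour of daily sleep
weekly.week1.control.mean_dominant_period_min   1440.0
weekly.week1.CCM.mean_dominant_period_min       1680.0
weekly.week1.control.mean_sleep_min_per_hr      38.7
```

The simulated misaligned arm dies sooner (its hazard ratio was programmed
at 1.94; at n = 30/arm the estimate is 1.91 with a wide CI), and the
dominant rest:activity period of each arm equals its imposed cycle length —
1440 min under LD12:12, 1680 min under LD14:14.

The same stages are exposed on the command line:

```bash
ccmpipe simulate --n-per-group 30 --seed 1 --out sim/
ccmpipe survival --monitors sim/ --metadata sim/metadata.tsv --out report/
ccmpipe de-compare --ccm wk3.tsv --aging aging.tsv
ccmpipe run-all --seed 1 --out report/
```

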