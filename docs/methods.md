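# Methods

This note documents the statistical procedures ccmpipe implements, the
generative model behind its synthetic cohorts, the defaults and why they
were chosen, and what the test suite does and does not demonstrate.

## Data model

A fly's record is a dense vector of non-negative beam-break counts at
1-min resolution with an absolute time origin (`BeamBreakSeries`).
Monitor files follow the common 42-column tab-delimited DAM layout
(index, date, time, status, five reserved columns, light flag, 32
channel counts); rows whose status code is not 1 are kept but treated as
zero-count minutes so that downstream sleep/death logic always sees a
gap-free series (the alternative — missing values — would force every
consumer to handle gaps; zero-fill is logged). Weekly tube transfers
produce short off-monitor gaps; concatenation zero-fills gaps up to a
configurable limit (default 120 min) and refuses larger ones as data
loss.

Light schedules are ordered epochs: LD epochs carry a cycle length T
(h), a photoperiod, and a lights-on anchor; DD epochs are dark
throughout. Zeitgeber time is hours since the most recent lights-on,
modulo T, and is undefined in DD. Intervals are half-open — lights are
on for ZT ∈ [0, photoperiod) — so boundary minutes are classified
unambiguously. A "week" is hours [168·(k−1), 168·k) from experiment
start for both arms; a 168-h week contains 7 complete 24-h cycles or 6
complete 28-h cycles, equalizing weekly light and dark exposure between
the arms.

## Death calling

Lifespan is the index of the last nonzero bin, after ghost filtering. A
nonzero bin is a ghost iff the nearest *retained* nonzero bin before it
is more than 720 min earlier **and** the nearest nonzero bin after it is
more than 720 min later or absent. Isolation is required on both sides
because a one-sided rule would delete genuine late-life activity bouts;
a pair of counts 13 h after the last activity but 30 min apart is
retained (the fly evidently lived that long). The scan is left-to-right
against retained activity, so a burst of counts after a long silence
protects itself. The first activity of a record is never a ghost: with
no prior activity there is no death for it to post-date. An all-zero
series is an error (no evidence of life), not a zero lifespan.

## Sleep and activity

Sleep is any run of ≥ 5 consecutive zero-count minutes; every minute of
such a run is a sleep minute, and maximal runs are the bout list.
Scoring operates on the ghost-filtered series truncated at the called
death, so post-mortem minutes are neither sleep nor wake. Weekly
summaries (sleep min/hr, counts/min) include only flies alive through
the whole week and divide by the full 10 080 min — only full-week
survivors are included, so alive-time equals week length. Full-life
summaries run over [0, lifespan − 3 days) because moribund flies'
inactivity is indistinguishable from sleep; lifespans ≤ 3 days are
flagged and excluded.

ZT profiles fold each surviving fly's week onto the cycle in 30-min bins
(48 bins at T = 24, 56 at T = 28), average within fly across the week's
complete cycles, then report mean ± SEM across flies (the figure-style
error is fly-to-fly, not day-to-day). An optional window offset
reproduces analyses anchored away from ZT0. Actograms are mean
normalized activity: each fly's minutes divided by its own window mean
(scale-invariant per fly), averaged across flies, rendered as 24-h
rows. The sleep–longevity association is Spearman's rank correlation
with a Fisher-z 95% CI using SE = 1/√(n − 3); this CI is an
approximation, adequate at cohort sizes of tens of flies.

## Rhythm analysis

The chi-squared periodogram evaluates every integer trial period P in
the search range. The series is folded into P phase columns; with
column means M_h, grand mean M̄, and n_h rows covering column h,

    Q(P) = N · Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)².

Under the no-rhythm null Q(P) is approximately χ² with P − 1 degrees of
freedom; the significance line is the 1 − α quantile (α = 0.01). The
dominant period is the argmax of Q over the range (smallest P on ties),
reported even when it falls below the significance line; rhythm power is
Q(dominant) minus the significance line there, a signed per-fly index of
rhythm strength with power > 0 marking significant rhythmicity.
Partial final cycles are kept — a column's mean uses however many rows
cover it — rather than truncating data. Because the autocorrelated
activity process violates the independence behind the χ² reference
distribution, the significance line is a field-standard convention, not
an exact test; power comparisons between groups are the intended use.

Search ranges are configuration, not science: 16–36 h for entrained
weeks (bracketing both 24-h and 28-h cycles so the estimate is free to
land on either) and 18–31 h for free-run. DD analysis excludes the
first 24 h after transfer to darkness (transfer perturbs behavior) and
requires 6 further days.

Numerical note: commercial periodogram software does not document its
exact normalization or its handling of partial columns, so low-order
digits of Q may differ between implementations; the test surface here is
oracle parity with the definition above, verified against a naive
fold-and-average implementation at 1e-9 relative tolerance.

## Survival modelling

Kaplan–Meier fits use the product-limit estimator with Greenwood
variance and log-log 95% CIs (via lifelines); the median is the smallest
time at which survival reaches 0.5 or below, undefined (infinite) if it
never does. Two-group comparisons use the standard 1-df log-rank test.

Cox models use the Efron approximation for tied event times — lifespans
cluster at day resolution, so ties are common and Breslow would bias
toward zero. The sleep covariate enters as hours of sleep per day
(min/hr × 24/60) so a unit change means one additional hour of daily
sleep. Constant covariates are rejected up front as unidentifiable. A
proportional-hazards violation (as reported for female cohorts, where
the treatment effect is front-loaded) is the caller's responsibility to
check; the model intentionally does not model time-varying effects.

Sleep matching is greedy and without replacement: controls sorted by
sleep value (ties by id), each matched to the nearest unmatched CCM fly
within 0.5 min/hr (ties nearer-then-lower-id). Greedy matching is
deterministic and order-stable, which we value over optimality: it can
occasionally pair one fly fewer than the true maximum bipartite
matching when three or more flies fall within a tolerance window in an
unfavorable arrangement. Reproducibility of the matched set across
reruns and platforms was the deciding criterion.

Helper arithmetic mirrors how cohort statistics are conventionally
reported: percent median-lifespan reduction 100·(ctrl − ccm)/ctrl
rounded half-up to one decimal; a hazard ratio's percent risk change
100·(HR − 1) rounded to integer; and the "equivalent sleep loss" of a
treatment, the h solving HR_sleep^(−h) = HR_treatment, i.e.
ln(HR_t)/(−ln(HR_s)), defined only when sleep is protective (HR_s < 1).

## Expression cross-classification

Inputs are two per-gene (log2FC, BH-adjusted p) tables from upstream
DESeq2 contrasts; DESeq2 itself, count filtering, and GO analysis are
out of scope. Genes with any missing field (padj NA from low-count
filtering, or absence from one table) are `unclassified`. For complete
genes: CCM FDR ≥ 0.1 → `not_ccm_significant`; otherwise same-direction
genes are `convergent` (aging FDR < 0.1) or `trend_same` (FDR ∈
[0.1, 0.3)), and opposite-direction genes are `opposite` when aging FDR
< 0.3. All padj intervals are half-open [lower, upper): a gene exactly
at 0.1 is a trend, one exactly at 0.3 is unclassified. The relaxed 0.3
cutoff for the opposite class deliberately catches genes that are
either truly counter-regulated by aging or simply untouched by it —
both patterns mark the CCM response as specific. A log2FC of exactly 0
has no direction and is unclassified with a warning. Fold-change
correlations between contrasts default to Spearman's rank (Pearson
available as an option, since both conventions appear in practice).

The package ships a curated 16-gene reference set (12 down with
misalignment/up with age, 4 the reverse) used as a worked example and a
fixed classification input.

## The synthetic cohort generator

The generator's purpose is closure: every estimator in the pipeline is
tested by recovering a quantity the simulator programmed. Its
components:

* **Activity.** A two-state (active/rest) Markov chain per minute. The
  stationary rest probability follows the schedule: day 0.50, night
  0.92, a siesta plateau of 0.85 for ±1.5 h around mid-day, and
  anticipation ramps that begin 8.5 h after the previous lighting
  transition and suppress rest by up to 85% at the next transition.
  Switching probabilities are p/τ into rest and (1 − p)/τ out, with
  τ = 8 min, giving mean night rest bouts of tens of minutes so that
  scoreable (≥ 5 min) sleep occurs at realistic rates (~35–40 min/hr
  overall). A pure inhomogeneous Poisson process would not produce
  long rest bouts and was rejected for that reason.
* **Clock-driven peaks.** Morning and evening activity peaks are
  modelled as added Poisson rate (6 and 2.5 counts/min for 20 min at
  dawn and dusk respectively). They are tied to circadian phase, not to
  the lights: in DD they recur at the fly's internal period (default
  24 h, configurable), continuing from the entrained phase at transfer.
  The asymmetry between the two peaks is deliberate — symmetric peaks
  make the half-cycle a competing fundamental and the periodogram can
  lock onto 1.5× the true period. Peak sizes, like the rest-curve
  contrast, were set so that period-recovery and power-monotonicity
  properties hold at small cohort sizes; no quantitative
  activity-intensity values were available to emulate.
* **Aging.** The rhythmic component (rest-curve contrast and peak
  rates) shrinks by a per-week factor (default 0.8) toward the cycle
  mean, so rhythm power declines with age while mean activity changes
  little.
* **Mortality.** Gompertz hazard a·e^{bt} with a = 0.0034/day,
  b = 0.15/day (median ≈ 23.0 days), multiplied by e^{log HR} for the
  misaligned arm (default log 1.94). The closed-form median
  log1p(b·ln2/(a·hr))/b serves as the oracle for recovery tests. Note
  that a Gompertz proportional-hazards effect of this size reduces the
  median by ~20%, somewhat more than the ~15% seen in real cohorts;
  the generator prioritizes a well-posed hazard-ratio recovery problem
  over matching both statistics at once, which proportional hazards
  cannot do.
* **Death and ghosts.** After the sampled death minute the record is
  silent. The ground-truth death (`true_death_minute`) is the last
  minute with a genuine count — the quantity death-calling should
  recover exactly. With per-fly probability `ghost_prob` (default
  0.05) a single count of 1 is placed uniformly at a minute more than
  12 h after death; if the record ends too soon for that, a warning is
  logged and no ghost is placed.
* **Determinism.** All draws flow through integer-seeded numpy
  Generator streams; per-fly streams derive from (master seed, arm,
  index), so cohorts are reproducible independent of simulation order
  and platform.

### What the simulator does not capture

Positional preference along the tube (a single mid-tube beam undercounts
activity away from the center), sex differences in baseline sleep,
temperature effects, masking responses beyond the dawn/dusk peaks,
inter-fly parameter heterogeneity (all flies in an arm share one
parameter set, so between-fly variance is purely stochastic), and any
mechanistic clock dynamics (no phase-response curve: DD phase is simply
continued proportionally from the entrained phase). Passing recovery
tests therefore demonstrates the estimators are correct on data
satisfying the pipeline's assumptions — not that real cohorts satisfy
them.

## Problem sizes and numerical choices

Survival recovery runs at 500 flies per arm (hazard-ratio standard
error ≈ 0.06 on the log scale, so the programmed HR 1.94 is recovered
within [1.7, 2.2] and a null cohort within [0.85, 1.18]); period
recovery uses 8–12 flies per condition; ghost/death closure uses 500
flies; oracle suites use hundreds of randomized small fixtures. The
Gompertz median check at n = 500 uses a ±0.5-day tolerance (≈ 2 Monte
Carlo standard errors). Rounding of reported percentages follows
half-up at the displayed precision, via decimal arithmetic to avoid
binary-float surprises. Dominant-period ties take the smallest period;
degenerate inputs (constant series, all-zero records, constant
covariates, rank-degenerate correlations) raise errors rather than
returning conventional values.
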