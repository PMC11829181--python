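# Methods

This note documents the models, parameters and numerical choices behind
`biphasic`, and what the synthetic validation does and does not show.

## Conventions

All data are nightly: one temperature per calendar (wake) date, no
time-of-day arithmetic. Cycle days are 1-based from the menses onset;
cycle length is the half-open day count between consecutive onsets, so
a 28-day cycle spans days 1–28. The ovulation date is the **last
follicular day**; follicular length is therefore the ovulation date's
cycle-day index and luteal length is `cycle_length − follicular`,
making the two phases tile the cycle exactly. This single convention is
used by the reference pipeline, both estimators and the evaluator, so
their outputs are directly comparable.

## Physiology detector

The detector consumes a fixed lookback of `lookback_days` nights
(default 60) ending at the analysis date, anchored so that the current
cycle's onset falls inside the window. Stages:

- **Sufficiency.** Strictly more than `max_missing_fraction` (default
  0.40) missing nights in the window is an `insufficient_data` failure;
  a window at exactly 40 % missing still runs. Nights absent from the
  series count as missing.
- **Normalization.** Valid nights are mean-centered. This makes the
  detector exactly invariant to constant offsets (sensor calibration,
  individual baseline), a property the tests assert.
- **Outlier rejection.** Nights strictly more than `outlier_sd` (default
  2) standard deviations from the window mean are invalidated. Mean and
  SD are computed per input window, not across users: a reusable tool
  has no access to a cross-user population statistic, and the window
  statistic adapts to each sensor's noise floor. Zero SD rejects
  nothing.
- **Linear imputation.** Interior gaps are linearly interpolated by
  date; leading/trailing gaps take the nearest valid value, since a
  linear fill is undefined with support on one side only. At least two
  valid nights are required.
- **Bandpass.** A Butterworth bandpass of order `bp_order` (default 2)
  with passband (`bp_low_cut`, `bp_high_cut`) = (1/60, 1/5) cycles/day,
  applied forward–backward (`sosfiltfilt`). The passband keeps the
  fundamental of a ~monthly biphasic wave (≈ 1/29 cycles/day) and its
  low harmonics while removing multi-month drift and night-scale noise.
  Zero-phase application matters: a causal filter would delay the rise
  and bias the estimated date late by a group-delay-dependent amount.
  Windows shorter than three impulse-response lengths are rejected as
  insufficient.
- **Hysteresis segmentation.** A two-threshold state machine scans
  forward from an initial *follicular* state (the window is anchored to
  a menses onset, and the early cycle is follicular by definition):
  switch to luteal at filtered value ≥ `hyst_high`, back to follicular
  at ≤ `hyst_low`; between thresholds the previous state persists,
  suppressing flicker from residual noise.
- **Postprocessing.** The candidate ovulation date is the day before
  the *last* follicular→luteal transition inside the current cycle
  (the most recent ovulation event wins; earlier transitions typically
  belong to the previous cycle). Estimates implying follicular length
  outside `follicular_range` = [10, 90] or luteal length outside
  `luteal_range` = [7, 17] days are rejected as explicit failures
  (`implausible_follicular` / `implausible_luteal`), as is the absence
  of any transition. When the next onset is not yet known, the luteal
  check uses days elapsed since the candidate; when it is known (always
  true in the evaluation harness, which analyses complete cycles as of
  the night before the next onset) the two formulations coincide.

### Threshold choice

The filter cutoffs and hysteresis thresholds are this package's own
engineering reconstruction — the commercial algorithm's tuned values
are not public — and every one of them is exposed in `DetectorConfig`.
The shipped hysteresis band (+0.05 / −0.10 °C) was tuned on simulated
cycles: the engage threshold must sit low enough that the filtered
crossing for a weak 0.3 °C rise (whose filtered step is ≈ 0.25–0.3 °C
peak-to-peak) is caught within a day of the true transition, and the
release threshold must sit deep enough that the bandpass's slow decay
of the luteal plateau cannot flip the state back mid-luteal and spawn a
spurious late transition near the window edge. A symmetric shallow band
showed exactly those two failure modes; the asymmetric band removes
both while remaining far above the filtered nightly noise floor
(≈ 0.02–0.04 °C for 0.1 °C raw noise).

With these defaults the detector carries a small late bias (0 to +1
day) on simulated cycles, because the first night labelled luteal is
the first night the smoothed rise clears the engage threshold — one
night after the last follicular day for fast rises. The within-±1-day
recovery guarantee absorbs this; applications needing an unbiased
estimator should calibrate `hyst_high` against their own reference
data.

## Calendar baseline

`estimate = period_start + (L − 12 − 1) days`, with `L` the median
cycle length over cycles starting within the trailing 183 days
(≈ 6 months; the trailing window is anchored to the target cycle's own
onset) after discarding lengths < 12 or > 90 days. The median of an
even count is the mean of the middle two values; a half-day median is
rounded toward the longer length so the estimate remains a calendar
date. No per-user luteal learning is attempted: 12 days is the
population-typical luteal length by construction of the method.

## Reference pipeline and screening

The benchmark ovulation date is the day after the last positive LH
test in the cycle. Cycles pass through screening rules in a fixed
order, each exclusion carrying the first reason tripped: incomplete
cycle (missing menses end or next onset) → no LH test → implausible
reference phase lengths (follicular outside [10, 90] or luteal outside
[8, 20] days) → overlapping algorithm input window (a user's second
cycle is dropped when its 60-night lookback, ending the night before
its next onset, intersects an already-accepted cycle's lookback) →
insufficient physiology (> 40 % missing in that lookback) → hormone
use → pregnancy. The fixed order makes exclusion tallies reproducible;
the tally conserves counts (eligible + per-reason exclusions = input).

## Synthetic cohorts

The generator emulates exactly the structure the detector assumes:

- **Cycle lengths.** A per-user mean is drawn from N(29.1, 3.4²) days
  (population values for cycling adults); per-cycle lengths jitter
  around it with SD `irregularity/√2`, so `irregularity` is the SD of
  consecutive-length differences. Defaults: irregularity 2 days.
- **Phase structure.** Luteal length ~ N(12, 1²) days, resampled into
  [8, 20] and capped so follicular ≥ 10 — reference plausibility holds
  by construction. True ovulation = cycle day `length − luteal`.
- **Temperature.** Per-user baseline ~ N(36.4, 0.15²) °C; a maintained
  rise with magnitude uniform on [0.3, 0.7] °C (the documented
  post-ovulatory range); a smoothstep ramp that is exactly 0 through
  the ovulation day and exactly 1 from `rise_ramp_days + 1` nights
  later (default 1, i.e. full plateau two nights after ovulation;
  0 gives a hard step); additive i.i.d. N(0, 0.1²) °C nightly noise;
  nights masked missing i.i.d. with probability 0.1. The plateau
  returns to baseline at the next onset.
- **Plumbing.** Ground truth is exported as a positive LH test the day
  *before* each true ovulation, so the reference pipeline reconstructs
  truth exactly rather than being bypassed. Each user gets one unlogged
  burn-in cycle so every reported cycle has a full lookback of
  physiology. Ages ~ N(32.8, 5.5²) clipped to [18, 52]. A single
  `numpy` generator seeded by `seed` drives all draws.

What the simulator does **not** model: within-night temperature
structure, autocorrelated sensor noise, fevers/alcohol/illness
artifacts, luteal-phase-deficiency profiles with damped rises,
slow seasonal drift, or realistic anovulatory physiology (a no-rise
flag exists for fuzzing only). Passing the synthetic recovery suites
therefore demonstrates correctness of the pipeline mechanics and
robustness to the modelled noise/missingness — not field accuracy on
real wearable data, which can only be established against external
references such as LH kits.

Simulation sizes in the validation suites (100 noise-free cycles, 200
noisy cycles, and a ~150-user, 8-cycle cohort for the end-to-end
comparison) were chosen to give stable rates and MAEs (binomial SE
≲ 1.5 % at n = 200) while keeping the whole suite fast.

## Evaluation layer

- Detection rate CI: normal approximation, p̂ ± 1.96·√(p̂(1−p̂)/n),
  clipped to [0, 100] %. Subgroup tables report the binomial SE on the
  same scale.
- MAE ± SEM over detected cycles (sample SD, ddof = 1; SEM 0 for a
  single error).
- Within-*k* proportions use *all* evaluable cycles as denominator —
  an undetected cycle counts as a miss. This reproduces the published
  convention for such counts.
- Fisher exact test (two-sided hypergeometric p) with the
  conditional-MLE odds ratio and exact CI — the estimator tied to the
  exact test; the sample OR is a worse match to published values on
  reconstructed tables. A table with an all-zero outcome column is
  reported as OR 1, p 1.
- Mann-Whitney U on absolute errors: exact enumeration when
  `n_a·n_b ≤ 10 000` and no cross-group ties, else the tie-corrected
  normal approximation. Cliff's δ = (#{a<b} − #{a>b})/(n_a·n_b),
  signed so positive δ means the first group's errors are smaller;
  it satisfies δ = 2·U_a/(n_a·n_b) − 1 with U_a counting pairs
  favouring the first group (half-ties included).
- Bonferroni: within each stratification family, m = number of
  non-reference classes with at least one detected cycle (classes a
  study would print as "—" contribute no comparison).
- Subgroup bins: length ≤21 / 22–26 / 27–31 / 32–35 / ≥36 days
  (reference: medium); variability = median |consecutive cycle-length
  difference| over the trailing 183 days, binned m ≤ 3 / 3 < m ≤ 7 /
  m > 7 days with half-integer medians resolved by those literal
  inequalities, unknown with fewer than two prior lengths (reference:
  typical); age 18–26 / 27–34 / 35–43 / ≥44 years (reference: 27–34).
  Ages under 18 raise: the approach is unvalidated in adolescents.
- Error sign convention: `estimated − reference` (positive = late).
  MAE uses absolute values, so the sign affects diagnostics only.

## Known limitations

- The detector's thresholds are reconstructions tuned on the simulator;
  transfer to any particular sensor requires recalibration.
- Anovulatory cycles are out of scope: the package provides no
  false-alarm rate, and a non-detection must not be read as evidence of
  anovulation.
- The reference is only as good as LH self-reports; the pipeline
  assumes ovulation follows the last positive test by one day.
- The overlap rule and trailing-window anchors (60-night lookback,
  183-day history) are documented choices where the underlying
  conventions are not standardised.
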