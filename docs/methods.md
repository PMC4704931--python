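# Methods

## The measurement problem

A basal-body-temperature (BBT) chart detects ovulation through a sustained
0.2–0.5 °C rise in waking temperature that begins shortly after ovulation
and lasts until the next menses.  The reference instrument is a digital
oral thermometer read once on waking.  A skin-temperature armband worn
overnight promises the same information without a morning ritual, but skin
temperature is systematically cooler than core temperature, far more
variable night-to-night, and sensitive to the sleep environment.  The
package quantifies whether the two instruments agree — first on the raw
temperatures, then on the downstream ovulatory/anovulatory/inconclusive
classification of whole cycles.

## Cycle model

Each simulated cycle is a step function plus noise:

* follicular plateau at `follicular_mean` (°C) from day 1 (first day of
  menses) through the day before ovulation;
* a single-day *nadir* at `follicular_mean − nadir_depth` on the ovulation
  day (`cycle_length − luteal_length`);
* a luteal plateau at `follicular_mean + shift_magnitude` from the next day
  through the last day of the cycle;
* anovulatory cycles (including the flat-cycle controls emulating
  oral-contraceptive users, whose temperature profile is not otherwise
  characterized) are the follicular plateau throughout.

Oral readings add i.i.d. Gaussian noise (`daily_noise_sd`) and are
quantised to the thermometer's 0.01 °C resolution.  Days are missing
independently with `missing_prob`; missing days stay missing (never
imputed).  Fever episodes add `fever_delta` on flagged days.

Default cohort distributions (used by `CohortConfig` unless overridden):
cycle length uniform 26–32 d, luteal length uniform 12–16 d (ovulatory
cycles therefore satisfy the ≥ 11-day criterion by construction),
shift uniform 0.2–0.5 °C, nadir depth uniform 0.1–0.3 °C, daily noise
SD 0.2 °C, missing probability 0.05/day, a 2-day +0.8 °C fever episode
with probability 0.15/cycle, 15 participants of whom 20 % are flat-cycle
controls and 85 % of the rest ovulate.  The follicular baseline (uniform
36.13–36.43 °C across participants) is set so that, after averaging the
ovulatory shift into the cycle, the cohort's oral grand mean is 36.4 °C
with SD ≈ 0.3 — the values the analysis is calibrated to reproduce.

## Device model

The armband's settled reading for an underlying temperature *T* is the
affine transform

```
level(T) = T − d(T),   d(T) = −bias_at_reference + prop_bias_slope · (T − reference_temp)
```

where `d(T)` is the oral-minus-armband difference.  Defaults:
`reference_temp` 36.4 °C, `bias_at_reference` −1.78 °C and
`prop_bias_slope` −0.2 (the difference grows at lower temperatures,
producing the negative Bland–Altman slope).  On top of the level sit:

* a per-night environmental shift, SD `night_effect_sd` = 1.15 °C.  This
  field is the deliberate extra degree of freedom of the device model:
  per-minute sensor noise averages out over any pre-waking window, so
  without a night-level random effect the armband's daily values would be
  nearly as tight as the oral ones (SD ≈ 0.3) instead of the ≈ 1.2 °C
  spread a skin sensor shows under real bedding/room variation — and the
  Bland–Altman cloud would show neither its width nor its slope;
* i.i.d. per-minute noise, SD 0.15 °C;
* a linear warm-up ramp from 2 °C below the level over the first
  `stabilization_minutes` (default 40; wearing periods of ~20 min are not
  enough for the sensor to settle, so the default sits safely above that);
* hard clipping to the recordable range 29.7–36.7 °C.  Clipping truncates
  the upper tail, lowering the mean ≈ 0.02 °C; `bias_at_reference` is
  −1.78 rather than −1.80 so the *post-clip* cohort reproduces an armband
  grand mean of 34.6 °C and a mean difference of ≈ 1.8 °C.

Nights are 8-h windows (480 one-minute samples) ending at a wake time
jittered uniformly ±60 min around 07:00 — wake times are irregular in
practice but their distribution is unreported, so a uniform jitter is the
least-structured choice.  The band is off-body after waking (10 trailing
samples) and on non-wear nights (probability `missing_prob`).

## Stream reduction

The wake time is the last on-body minute (the protocol is to remove the
band immediately on waking; an explicitly recorded wake time, if present,
takes precedence, since vendor wake-detection algorithms are proprietary).
The daily armband value for interval *k* ∈ {10, 30, 60, 90, 120} min is the
mean of on-body samples in the half-open window `[wake − k, wake)` — the
waking minute itself is excluded, being "prior to" waking.  Windows with
under 50 % on-body coverage yield a missing value; partial-wear handling
is otherwise unreported, and 50 % is the package's documented choice.
Off-body samples inside the window are always excluded.

## Classification rules

**Visual criteria** (applied programmatically; no human raters):

1. *Biphasic*: the first day `d` in a ±4-day window around the expected
   ovulation day such that the temperatures on `d`, `d+1`, `d+2` each
   exceed the **maximum** of the six preceding usable temperatures by
   strictly more than 0.2 °C.  The expected ovulation day is
   `cycle_length − 13`, i.e. the day with exactly 14 days (two weeks)
   remaining; the comparison against the maximum (rather than the mean)
   of the six is the classical three-over-six reading of the rule, and
   the ±4-day window half-width is the package's choice, both fixed here
   because the conventions are not otherwise pinned down.
2. *Adequate thermal shift*: the elevation spans ≥ 11 days through cycle
   end; every usable luteal temperature stays strictly above the pre-shift
   reference (the maximum of the six preceding usable days — a value at or
   below it is a "deep fall"); and the rise completes in < 2 days (the
   last usable pre-shift day is the day before the shift).
3. *Nadir*: the lowest of the three days before the shift, if strictly
   below the mean of the six pre-shift days — supportive evidence only;
   its absence can never force an anovulatory call.

Ovulatory requires 1 and 2; anovulatory is a decisive failure of either on
adequately complete data; inconclusive covers incomplete data (< 17
recorded days or > 20 % of days missing — the 17-day floor mirrors the
analyzability threshold used for exclusions), an unanchorable window (next
menses unobserved), or undeterminable criteria (no candidate day with six
usable predecessors; more than two missing luteal days).  Fever-flagged
days are excluded from every criterion computation.

**Quantitative mean-temperature rule**: compute the cycle mean over usable
days; the cycle is ovulatory if some day `d` starts a 3-day run strictly
above the mean with at least 11 days from `d` to cycle end above the mean
and none more than 0.1 °C below it.  The classical mean-temperature method
is cited in the charting literature without a complete operational
definition, so this rule is a documented stand-in; the 0.1 °C tolerance
prevents a single noise sample from vetoing an otherwise clear luteal
elevation.  Results that depend on this rule inherit that caveat.

**Adjudication**: two concordant raters decide; two discordant raters
escalate to a third; three raters decide by mode, with a three-way tie
inconclusive.

## Agreement statistics

Spearman correlation (average-rank ties, two-sided p, listwise deletion)
and the Bland–Altman quantities come from scipy; the kappa point estimate
is computed by statsmodels and embedded in the package's result type.
Limits of agreement use the standard 1.96 multiplier.  Kappa is unweighted
(nominal categories).  Per-category agreement is the diagonal cell over
the total n — the convention under which the per-category percentages sum
to the overall agreement.  When both raters place every cycle in the same
single category, expected agreement is 1 and kappa is reported as
*undefined*, distinct from 0.

## Numerical choices

* All strict comparisons use a 10⁻⁹ guard band, so a shift of exactly
  0.2 °C (stored as a float) never counts as "> 0.2 °C".
* Temperatures are quantised to 0.01 °C at generation; CSV output writes
  full-precision `repr`, making write→read round-trips lossless and
  same-seed outputs byte-identical.
* Cohort generation spawns one child seed per participant from a single
  seed sequence, so results are reproducible and participant streams are
  independent.
* The Bland–Altman slope of a degenerate cloud (constant means, constant
  differences) is 0 by convention.
* Report serialisation rounds kappa to 4 decimals and percentages to 2,
  matching the display precision of the statistics it reports.

## Verification problem sizes

The test suite checks simulator calibration on one 15-participant cohort
(the studied cohort size) using cluster-robust standard errors — the SD of
participant-level means over √15 — because nights within a participant
share that participant's baseline and the armband's night effects, and a
pooled-days SE would pretend ~420 independent observations.  Classifier
recovery is assessed on 500 cycles sampled from the low-noise regime
(shift uniform 0.3–0.5 °C, daily noise SD uniform 0–0.05 °C, complete
charts): the recovery guarantee is a property of that parameter region, so
the test samples the region rather than a single corner.  Oracle
equivalence runs 1,000 random contingency tables against a brute-force
pair-expansion kappa and 200 random cycles against an exhaustive
window-scanning shift detector.

## What the generator does and does not emulate

It emulates: biphasic and flat cycles with known ground truth; thermometer
quantisation and noise; compliance gaps (missing days, non-wear nights);
fever days; and a wearable with large negative temperature-dependent bias,
night-level environmental variability, warm-up, and range clipping.

It does not emulate: physiological thermoregulation or circadian structure
beyond the warm-up ramp; shared day-to-day physiological variation that
would move both instruments together — as a result the simulated
cross-device correlation (ρ ≈ 0.1–0.2) sits below what field data show
(≈ 0.3–0.4), while the interval-to-interval correlations sit above
(≈ 1.0 vs ≈ 0.8–1.0) because no within-night drift separates the
windows; bedding/room covariates (subsumed into the night effect); or
behavioural correlation between oral and armband compliance.  Passing
tests therefore demonstrate the pipeline's correctness and calibration on
this generative model, not the field performance of any particular device.

## Known limitations

* The quantitative rule is a stand-in for an incompletely specified
  method; its per-cycle calls should not be over-interpreted.
* The visual criteria are fully deterministic and so cannot reproduce
  inter-rater variability; the adjudication operation exists for
  externally supplied rater call files.
* Wake detection assumes removal on waking; sleep-staging wake estimates
  must be supplied explicitly.
* Timestamps are naive local time; time-zone changes mid-cycle are out of
  scope.
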