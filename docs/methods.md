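# Methods

## Kinematic metrics

All metrics operate on the per-sample Euclidean norm of the tri-axial
acceleration.  Gravity is deliberately **not** subtracted: the magnitude
series has a quiet floor near 9.81 m/s² punctuated by movement peaks, and the
MET regression below was evidently fitted on raw magnitudes (its intercept of
−15 maps a resting RMS of ~9.8 m/s² to ~2.6 METs and only goes negative below
8.33 m/s²).  Both the scalar reduction and the regression coefficients are
configurable.

**Peak detection.** z-scores are computed against the segment-global mean and
*population* standard deviation (a rolling-window variant is available for
non-stationary segments).  A peak is an interior local maximum of z with
z ≥ `z_threshold` (default 2.0), thinned greedily in time order so that kept
peaks are at least `min_separation_s` apart — the earlier peak always wins.
The separation is enforced in whole samples (`ceil(min_separation_s / dt)`),
which makes the boundary case exact instead of dependent on floating-point
rounding of timestamps.

The default dead time is **0.1 s**.  A longer dead time materially undercounts
at realistic exergame action rates: for Poisson-timed events at rate λ the
greedy thinning behaves as a Type-I counter with throughput λ/(1 + λτ), so at
λ = 0.5 Hz a τ of 0.25 s discards ~11 % of true events while τ = 0.1 s
discards ~5 %.  0.1 s still exceeds the above-threshold apex width of the
synthetic bursts (about 0.17 s wide in total, with candidate maxima clustered
within a few samples of the apex), so a single burst is not double-counted.
Measured on full-length simulated segments the detector recovers 93–98 % of
true events.

**METs and energy.** METs = 1.8 × RMS − 15 is used as printed, clamped at
zero (the raw value is kept alongside for auditing); the units of the
regression are device-specific and the coefficients are parameters.  Energy
is 1.05 × METs × duration(h) × weight(kg), i.e. the hourly rate integrated
over the segment duration.

**Cross-sensor aggregation.** The study reports one value per metric per
game/date range without a cross-sensor rule.  The aggregate here takes the
mean action count and mean RMS over the five sensors, the maximum of the
per-sensor maxima, and derives METs/energy from the aggregate RMS.  Weekly
values are means over that week's segments.

## Well-being classification

Subscale sums use the standard MHC-SF structure — emotional items 1–3,
social 4–8, psychological 9–14 (the 11 eudemonic items are social +
psychological); the item-to-subscale map is configuration.  Classification is
the two-group rule only (mentally well vs moderate, no languishing category),
with a *sign* defined as category ≥ 4 ("5–6 times a week" or "every day").
Group membership for trend stratification is fixed at the week-1 response by
default, so the same participants are compared across weeks; per-week
reclassification is available.  Missing items are a hard error — no
imputation unless explicitly configured.

## Nutrition aggregation

Weeks are half-open 7-day bins anchored at the study start date.  Weekly
statistics are descriptive cohort means with record counts; missing days
drop out of the denominator, out-of-window records are excluded with a
warning, and empty cells are reported as missing, never zero.  No
significance testing is applied to nutrition trends.

## Pre/post statistics

Paired t-tests are two-tailed on pre − post differences (improvement gives a
negative t), df = n − 1, with zero-variance differences raised as degenerate
rather than silently reported.  Survey summaries use sample SDs (n − 1);
population σ appears only inside peak detection.  Cohen's d uses the pooled
SD, `(post − pre)/sqrt((sd_pre² + sd_post²)/2)`; the sign is retained
internally and the magnitude is reported, rounded half-away-from-zero to two
decimals at the report layer only.  Raw per-item p-values are reported
without multiplicity adjustment (an optional Holm correction is off by
default), matching how such small pre/post item batteries are conventionally
reported.

A cohort-level "overall enhancement" statistic is deliberately not derived
from two group-level percentages: it is only computable from per-participant
data, which the pipeline produces when it has them (`metric_group_trends` on
the full metrics table).

## Synthetic cohort generator

The generator emulates the study conditions: 48 participants across 4 arms
(30 completing both surveys), 4 weekly sessions of 3 exergames, 5 sensors per
participant (both distal forearms, waist at L4, both feet).

* **IMU signal**: per-axis Gaussian sensor noise (SD 0.3 m/s²) around zero,
  gravity (9.81 m/s²) on the vertical axis, plus half-sine bursts of 0.3 s
  width and 8 m/s² amplitude at Poisson-timed onsets (0.5 events/s), shared
  across the five sensors of a session.  The 50 Hz sampling rate is a typical
  consumer-IMU default; none of rate, amplitude, noise or burst shape is
  dictated by the metrics, and all are configurable.  True event onsets are
  emitted with each frame.
* **Weekly intensity growth**: the whole signal of a session is scaled by a
  factor interpolating linearly from 1 (week 1) to 1 + g (final week), with
  g = 2.14 % for the mentally-well group and 9.60 % for the moderate group by
  default — so expected maximum and RMS acceleration change by exactly g over
  the study.  Scaling the full signal (gravity included) is a deliberate
  simplification: it makes the configured growth an exact property of every
  scale-equivariant metric rather than an approximation.
* **Surveys**: each item's (pre, post) pair is bivariate normal with the
  configured moments and within-subject correlation (default 0.5), then
  rounded half-away-from-zero and clipped to the 1–5 Likert scale.  The
  configured moments are *latent-scale* moments: discretization and clipping
  bias the observed moments (clipping alone is material when a mean sits
  within ~1.3 SD of the scale edge), so parameter-recovery checks run on the
  emitted latent values.  Item defaults are the seven published pre/post
  moment pairs.
* **Questionnaires**: item categories are drawn from per-group categorical
  profiles; the defaults give the well-type profile an 80 % per-item
  probability of a "sign" and the moderate-type 15 %, so ~98 % of well-type
  participants classify as mentally well and essentially no moderate-type
  do.  True group labels are emitted.
* **Nutrition**: daily value = baseline + drift × (week − 1) + Gaussian noise,
  truncated at zero, emitted as continuous amounts.  Defaults: steady milk
  (1.5 servings), rising water (6 cups + 0.5/week), rising balanced meals
  (1.0 + 0.3/week).

What the generator does **not** emulate: biomechanically realistic gait or
arm kinematics, orientation/gyroscope dynamics, device dropout, attrition
mechanisms, learning effects beyond the linear intensity scale, or
item-level response styles.  Passing tests therefore demonstrate that the
*analysis pathway* is correct and well-calibrated under the stated
statistical structure — not that the metrics are valid measurements of human
movement.

## Numerical choices

* Report-layer rounding is half-away-from-zero (`Decimal`, not banker's
  rounding); internal values are never rounded.
* Peak separation is an integer-sample rule (see above); on equal z within a
  window the earlier sample wins.
* Degenerate inputs raise typed errors (`DegenerateSignalError`,
  `DegenerateTestError`) except where a safe default is stated: a constant
  signal yields zero peaks with a warning, an all-equal pre/post item is
  summarized with d = 0 and a flagged (NaN) t.
* All randomness derives from a single integer seed through
  `numpy.random.SeedSequence` with fixed child keys per stream (roster, IMU
  session, survey, questionnaire, nutrition), so outputs are bit-reproducible
  and adding a new stream cannot silently shift existing ones.

## Problem sizes in the test suite

Statistical checks are run at sizes chosen for tight Monte-Carlo error:
effect-size recovery and type-I calibration use 2,000 replicates of n = 30;
the intensity-growth recovery check uses 100 seeded cohorts of 48
participants with 60 s segments at 25 Hz and one game per session (the
growth property is scale-exact, so segment length and game count affect only
variance); the demo pipeline uses 8 participants with 15 s segments.  Unit
and oracle tests cover series up to n = 10,000.

## Known limitations

* The MET regression's units/scaling are device-specific; with other
  hardware the coefficients (1.8, −15, 1.05) must be recalibrated.
* Between-arm comparisons are out of scope: arm labels are carried through
  but not analysed.
* The exact wording of the 14 questionnaire items is treated as opaque; the
  package scores indexed signs, not instruments.
* Goal adherence uses "value ≥ target on logged days" — it cannot distinguish
  an unlogged day from a missed goal.
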