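# kinwell

Analysis pipeline for exergame-based health interventions in older adults,
built around four data streams collected over a multi-week study: body-worn
inertial sensors (IMUs) recorded during gameplay, weekly 14-item
well-being questionnaires (an MHC-SF adaptation), daily nutrition logs, and
paired pre/post attitude surveys.

It is written for researchers running or re-analysing pre/post exergame
cohort studies who need the full pathway — raw tri-axial acceleration to
kinematic metrics, questionnaire scores to a flourishing classification,
daily logs to weekly trends, and paired surveys to effect sizes — as tested,
seeded, reproducible code.  A synthetic cohort generator with ground-truth
labels stands in for raw study data, so every stage can be exercised and
validated end to end.

## The measures

**Kinematic metrics** per (participant, game, session) segment, computed on
the Euclidean magnitude `a_i = ||(ax, ay, az)_i||` of each sensor's tri-axial
acceleration (gravity not subtracted):

- *z-score peak detection*: `z = (X − μ)/σ` over the segment (population σ);
  a peak is a local maximum with `z ≥ 2` and at least 0.1 s from the previous
  kept peak,
- *action count* = (number of peaks) / (number of samples),
- *maximum acceleration* = `max(a)`,
- *RMS acceleration* = `sqrt(mean(a_i²))` — the movement-intensity proxy,
- *METs* = `1.8 × RMS − 15` (clamped at 0; raw value retained),
- *energy* = `1.05 × METs × D × W` kcal, with `D` the duration in hours and
  `W` the body mass in kg.

**Well-being classification**: a participant is *mentally well* when at least
1 of the 3 hedonic items and at least 6 of the 11 eudemonic items are
reported "every day" or "5–6 times a week" (category ≥ 4 on the 0–5
frequency scale); otherwise *moderate*.

**Pre/post statistics**: two-tailed paired t-tests with the pre − post sign
convention (improvement ⇒ negative t), pooled-SD Cohen's d

    d = (post_mean − pre_mean) / sqrt((pre_sd² + post_sd²)/2),

and percent change `100 × (after − before)/before`, with group-stratified
weekly trends of the kinematic metrics.

## Worked example

```python
import kinwell as kw

# pooled effect size from a survey item's pre/post moments
d = kw.cohens_d_pooled(3.18, 0.79, 3.95, 0.82)
print(round(d, 2))                     # 0.96  (large effect)

# group-level improvement in maximum acceleration, week 1 -> week 4
print(kw.percent_change(18.7, 19.1))   # 2.14
print(kw.percent_change(17.7, 19.4))   # 9.6

# one simulated 60 s game segment, five sensors, and its aggregate metrics
cfg = kw.CohortConfig(seed=1, segment_duration_s=60.0, sampling_hz=50.0)
frames = kw.simulate_imu_session(cfg, "P01", 1, "fruit_ninja",
                                 group="mentally_well")
m = kw.session_metrics(frames, weight_kg=65.0)["AGGREGATE"]
print(f"{m.action_count:.4f} {m.max_acceleration:.2f} "
      f"{m.rms_acceleration:.2f} {m.mets:.2f} {m.energy_kcal:.2f}")
# 0.0111 21.66 10.91 4.65 5.28
```

The last line reads: 0.0111 detected movement peaks per sample (≈ 33 actions
in 60 s at 50 Hz), a 21.66 m/s² maximum, 10.91 m/s² RMS intensity, 4.65 METs
and 5.28 kcal expended over the minute by a 65 kg participant.  The simulated
segment contained 34 true movement events.

## Command line

```bash
kinwell simulate --seed 3 --out raw/           # synthetic cohort CSVs
kinwell metrics  --input raw/sensors.csv --out metrics.csv
kinwell classify --input raw/mhcsf.csv --basis week1 --out wellbeing.csv
kinwell nutrition --input raw/nutrition.csv --start 2024-01-01 --out nut.csv
kinwell stats --survey raw/survey.csv --metrics metrics.csv \
              --classes wellbeing.csv --out report/
kinwell run --seed 1 --out demo/               # the whole pipeline
```

`kinwell run` writes all stage CSVs, a `summary.json`, and a `manifest.json`
with the SHA-256 of every output: two runs with the same config and seed are
byte-identical.

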