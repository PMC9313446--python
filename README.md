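# lanelapse

Simulation and analysis of **sustained attention in a continuous
lane-keeping driving task**.

## The problem

Classic continuous performance tests register discrete hits and misses,
which summarizes attention as a single score. A richer alternative is a
simple driving game: the participant steers a car down a circuit of
straights and curves while the car's lateral position is recorded
continuously (50 Hz, 34,496 samples over an 11.5-minute session). The
signed distance from the road centerline is then a dense behavioral
time series in which attention lapses are visible as *sustained*
excursions — and their onset and recovery can be localized in time,
which matters for populations such as children assessed for ADHD.

No recordings of real participants are distributed with this package.
Instead, a fully specified simulator plus synthetic driver models stand
in for a cohort, so every stage of the analysis chain can be exercised
and tested end to end:

* **Task simulator** — a circuit of 58 curves and 58 straights; keys
  move the car laterally at 10 m/s; curves push it outward at 0.45 of
  that speed; the car cannot leave the road (it rides the edge, raising
  a collision flag).
* **Driver models** — a deadband + reaction-delay + motor-noise
  controller with planned attention lapses (during a lapse no key is
  pressed and the car drifts to the edge). Four archetypes: uniformly
  good, uniformly poor, attention lost mid-task, alternating. A cohort
  generator assigns ages 7–17 with skill improving with age.
* **Analysis chain** —
  * per-age boxplot statistics of absolute error
    (Q1, median, Q3, IQR, Tukey fences `Q1 − 1.5·IQR`, `Q3 + 1.5·IQR`);
  * k-means clustering of 10 s-binned error trajectories per age group,
    with the cluster count chosen at the scree's elbow (maximum second
    difference of within-cluster inertia);
  * attention localization: positions strictly outside the age group's
    fences are outliers; maximal runs of consecutive outliers lasting
    ≥ 1 s are *sustained errors*; the first such run marks the loss of
    attention and its end the recovery.

## Worked example

```bash
$ lanelapse worked-example
non-outlier position interval: [-2.4, 2.6]
sustained errors start at observation 20617, i.e. after 6.87 min
attention recovered from observation 31008 after 3.46 min of inattention
attention maintained until the end of the task: yes
```

A standard-length session whose positions lie outside the 11-year-old
non-outlier interval `[-2.4, 2.6]` exactly on observations
`[20617, 31008)` is pushed through the pipeline: the first sustained
error begins at observation 20,617 (20,617 / 50 / 60 = 6.87 min into
the task), attention is recovered at observation 31,008, and the
inattentive episode lasts (31,008 − 20,617) / 3,000 = 3.46 min.

From Python, the same demonstration plus full synthetic analyses:

```python
from lanelapse import compute_attention, generate_archetype_group

cohort = generate_archetype_group(
    {"uniform_good": 7, "onset_loss": 1},
    age=11, seed=2, params={"onset_s": 412.34},
)
profile = compute_attention(cohort, "11-8")
print(profile.first_loss_minutes)   # 6.88 — the planted onset is 6.87 min
```

The `examples/` directory holds one short script per capability
(simulation, age boxplots, clustering, attention profiling, the worked
example); each prints the numbers it computes and a line on what they
mean. The `lanelapse` CLI exposes `simulate` (write a synthetic cohort
as CSV files), `analyze` (full report directory with tables, JSON
attention profiles and figures) and `worked-example`.

## Session file format

Sessions are plain CSV with `#`-prefixed metadata lines
(`participant_id`, `age`, `sample_rate`, `config`), a header
`index,t,position,road_direction,key,collision`, positions and times at
fixed 6-decimal precision, `road_direction ∈ {S,L,R}`,
`key ∈ {left,right,none}`, `collision ∈ {0,1}`. Write → read → write is
byte-identical. Cohorts are a `manifest.csv`
(`participant_id,age,session_file,…`) with session files resolved
relative to it.

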