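# Methods

## Task model

The driving task is reduced to the single degree of freedom the
analysis uses: the car's signed lateral offset from the road
centerline (positive = right). The circuit is an ordered list of timed
segments — straight, left curve, right curve — and the car advances by
explicit Euler steps at the recording tick (dt = 1/50 s; dynamics and
recording share one clock):

    x[t+dt] = clamp( x[t] + dt * (v_key + v_drift), -w, +w )

with `v_key ∈ {-10, 0, +10}` m/s for the left/none/right key,
`v_drift = ±0.45 × 10` m/s on curves (signed toward the outside: a
left curve pushes right), 0 on straights, and `w` the road half-width.
The stated lateral "force" has velocity units, so the model is
kinematic — velocities, not accelerations; this is the simplest model
consistent with the printed constants. The clamp encodes that the car
cannot leave the road; the collision flag is true exactly when the
clamp changed the value on that step.

The default test circuit has 58 curves and 58 straights, alternating
starting with a straight (an arbitrary but fixed convention, echoed in
the track's JSON metadata), with curve handedness drawn 50/50 from a
seed. Equal segments are used throughout. The session is defined as
exactly 34,496 samples at 50 Hz (689.92 s) — the sample count, not the
nominal 11.5 min, is the hard constraint, since the analysis requires
identical series lengths; the default segment duration is therefore
689.92 / 116 ≈ 5.9476 s so the circuit is tiled exactly. The 40 s
tutorial circuit (4 curves + 4 straights) keeps 5 s segments.

### Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| lateral_speed | 10 | m/s | key-commanded lateral velocity |
| curve_drift_ratio | 0.45 | – | outward drift as a fraction of lateral_speed |
| half_width | 3.0 | m | road half-width (clamp bound) |
| sample_rate | 50 | Hz | recording and integration frequency |
| samples_per_session | 34,496 | – | fixed series length |

The road half-width is not derivable from the task constants; 3.0 m is
chosen so that positions beyond a plausible non-outlier interval like
[−2.4, 2.6] m remain attainable with headroom for edge-riding, and it
is configurable.

## Synthetic drivers

Real participants are unavailable, so a minimal closed-loop controller
generates the cohort. While attentive, the driver observes the
position `reaction_delay` seconds in the past (history padded with the
start position), presses nothing while that observation is inside a
`deadband` around the centerline, otherwise presses toward the
centerline; with per-tick probability `miskey_prob` the intended key
is replaced by a uniformly random one (motor noise). While lapsed, the
driver presses nothing at all — parameter-free, and on curves the
drift then pins the car to the edge within `w / 4.5 ≈ 0.67` s, which
is what makes planted lapse onsets sharply recoverable.

Lapse schedules define four archetypes: empty (uniformly good), the
whole session (uniformly poor), `[onset, end)` (attention lost
mid-task; onset either fixed or drawn from a fraction range of the
session), and alternating attentive/inattentive stretches with
durations drawn uniformly from [0.5, 1.5] × mean (defaults 120 s
on / 90 s off; the bounded draws guarantee at least two lapse
intervals per standard session, so the alternating pattern is always
visible).

Skill varies with age linearly from 7 to 17 years: reaction delay
0.14 → 0.05 s, deadband 0.60 → 0.30 m, slip probability 0.030 → 0.004
per tick, each multiplied by a per-participant jitter drawn uniformly
from [0.8, 1.2]. These values were set once from two qualitative
requirements: the attentive oscillation amplitude (≈ deadband +
4.5 × delay on curves) must shrink with age, giving the expected
negative age–error correlation, and even the youngest attentive driver
must stay well inside the Tukey fences of their age group so that only
genuine lapses produce sustained out-of-fence runs. Ages are drawn
uniformly over the integer range; matching any particular empirical
age distribution's moments is not attempted. The default archetype mix
is 70% uniformly good, 10% each of the other three — most children
perform unremarkably, a few show each atypical pattern.

Determinism: each session pre-draws its full random streams
(`rng.random(n)` then `rng.integers(0, 3, n)` from
`default_rng(seed)`), indexed by tick; lapsed ticks leave their draws
unused. The cohort generator documents its per-participant draw order
(age, archetype, jitters, schedule seed, session seed), so cohorts and
sessions are pure functions of (spec, seed).

## Analysis chain

**Error metric.** The error at each sample is the absolute lateral
position. Quartiles everywhere use linear interpolation between order
statistics (quantile type 7, numpy's default); the convention is
recorded in exported tables because the fences depend on it. Fences
are `Q1 − 1.5·IQR` and `Q3 + 1.5·IQR`; outliers are *strictly*
outside, so a value exactly on a fence is not outlying.

**Age grouping.** Ages are grouped by integer year. The age boxplot
table pools all samples of all participants of an age (absolute
error); the attention fences pool the same participants' *signed*
positions — the signed convention is required because attentive
driving need not be symmetric around the centerline, so the fence
interval can be asymmetric. The analyzed participant is included in
their own fence pool by default (the group is defined as "all children
of that age"); a leave-one-out flag supports sensitivity analysis.

**Sustained runs.** A sample is inattentive-candidate when outside the
fences; maximal runs of consecutive candidates lasting at least 1 s
(≥ 50 samples, inclusive — "a second or more") are sustained errors;
shorter runs are instantaneous atypicalities and are discarded. The
threshold is configurable and task-specific. Runs are half-open index
intervals [start, end): `end` is the first non-outlying observation,
read as the recovery point. Runs separated by any attentive gap remain
distinct — no bridging rule is applied. The attention profile reports
the first run's start in minutes (two decimals in displays), the total
inattentive time as the sum of run durations computed *from the
indices*, and whether the last run touches the final sample.

**Clustering.** Participants of one age are represented by 10 s-binned
mean absolute error (68 features for a standard session; trailing
partial bin dropped). The binning preserves the temporal patterns that
distinguish archetypes while avoiding 34,496-dimensional distances; no
per-bin normalization is applied since all features share units
(meters). K-means uses k-means++ seeding and best-of-restarts
(scikit-learn); the scree over k = 1..k_max is guaranteed
non-increasing by additionally initializing each k from the (k−1)
solution's centers plus the point farthest from its center. The
cluster count is selected by the maximum second difference
`(W(k−1) − W(k)) − (W(k) − W(k+1))` over interior k, ties toward
smaller k — a testable surrogate for reading the elbow by eye; the
scree table is always emitted for human inspection. Singleton clusters
are reported by member id (a child behaving unlike all peers), and a
near-zero total inertia is flagged as "no structure" (the tie-break
then selects k = 2 vacuously).

A note on planted-structure experiments: under the second-difference
rule the planted k is only recovered when consecutive inertia drops
are comparable. The three-archetype recovery experiment therefore uses
3 good + 2 poor + 3 onset-loss drivers with onset at 412.34 s; with a
single atypical driver the entire first drop concentrates at k = 2 and
the rule — correctly, for that geometry — selects 2. The
lone-poor-driver experiment (7 good + 1 poor) exploits exactly that to
isolate the atypical driver as a singleton at k = 2.

## Numerical and degenerate-input choices

* Boundary values equal to a fence are non-outlying (strict
  inequalities); equal fences (a zero-IQR pool) are allowed with a
  warning, every deviation from the common value then being an
  outlier.
* `segment_at` uses half-open segment intervals; the session must be
  fully covered by the track, else simulation refuses to start.
* The one-tick overshoot bound for a zero-delay driver is
  `deadband + (0.45×10 + 10)/50` m; tests use it as a closed form.
* The minimum run length in samples is `ceil(min_duration ×
  sample_rate)` with a 1e-9 guard so exact products are not pushed up
  by floating-point noise.
* Sessions are serialized at fixed 6-decimal precision; the round trip
  is byte-exact and the quantization (5×10⁻⁷ m) is far below any
  analysis tolerance.

## Problem sizes

The reproduction experiments use 20 replicate cohorts per question
(7–8 full-length sessions each) and a 63-participant default cohort —
enough replication for rates quoted in steps of 5% while keeping a
full run of tests plus acceptance script around a minute of CPU. Unit
and property tests use a 40 s / 2,000-sample task configuration where
session length is irrelevant to the property under test.

## What the synthetic cohort does and does not show

The generator reproduces the *statistical structure* the analysis
assumes: an age–skill gradient, heavy-tailed position distributions
under lapses, and the four archetypal temporal patterns. It does not
claim that real children implement a deadband/delay controller, that
real lapses are all-or-none, or that real onset times are sharp;
passing tests therefore validate the analysis pipeline (fences, run
detection, clustering, selection rules) and its recovery of planted
ground truth — not any clinical property of real recordings. Metrics
of hyperactivity or impulsivity are out of scope.
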