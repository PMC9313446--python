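"""Synthetic driver models and cohort generation.

No recordings from the original study population are available, so this
module stands in for it: a closed-loop driver policy (deadband +
reaction-delay + motor-noise controller) steers the car of
:mod:`lanelapse.track`, interrupted by planned attention lapses during
which no key is pressed and the car drifts to the road edge on curves.

Four behavioral archetypes parameterize the lapse schedules:

``uniform_good``
    attentive for the whole session (empty schedule);
``uniform_poor``
    inattentive for the whole session;
``onset_loss``
    attentive until an onset time, inattentive to the end;
``alternating``
    alternating attentive / inattentive intervals.

The cohort generator assigns each synthetic participant an age, an
archetype and a skill level that improves with age (shorter reaction
delay, smaller deadband, fewer motor slips), reproducing the age–error
gradient the analysis is designed to detect.

RNG consumption contract (needed for seeded-replay tests)
---------------------------------------------------------
``simulate_session`` creates ``numpy.random.default_rng(seed)`` and draws,
in order, ``rng.random(n)`` (per-tick motor-slip uniforms) and
``rng.integers(0, 3, n)`` (per-tick replacement keys, 0=none 1=left
2=right).  Both arrays are indexed by tick; entries for lapsed ticks are
drawn but unused.  The standalone :func:`attentive_policy`, when given an
rng, consumes one ``random()`` and one ``integers(0, 3)`` per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .session_io import Cohort, SessionRecord
from .track import (
    CarState,
    DynamicsConfig,
    Key,
    Track,
    default_track,
)

ARCHETYPES = ("uniform_good", "uniform_poor", "onset_loss", "alternating")

_KEY_NAMES = np.array(["none", "left", "right"])


@dataclass(frozen=True)
class LapseSchedule:
    """Planned inattentive intervals, disjoint sorted [start_s, end_s)."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", iv)
        prev_end = -math.inf
        for a, b in iv:
            if not (0 <= a < b):
                raise InvalidParameterError(f"bad lapse interval [{a}, {b})")
            if a < prev_end:
                raise InvalidParameterError("lapse intervals must be sorted and disjoint")
            prev_end = b

    def tick_mask(self, n: int, sample_rate: float) -> np.ndarray:
        """Boolean mask over n ticks: True where t = i/sample_rate is lapsed."""
        mask = np.zeros(n, dtype=bool)
        for a, b in self.intervals:
            i0 = max(0, math.ceil(a * sample_rate - 1e-9))
            i1 = min(n, math.ceil(b * sample_rate - 1e-9))
            mask[i0:i1] = True
        return mask

    @property
    def total_seconds(self) -> float:
        return sum(b - a for a, b in self.intervals)


@dataclass(frozen=True)
class DriverProfile:
    """Closed-loop controller parameters.

    reaction_delay
        Seconds between a position and the driver acting on it.
    deadband
        No correction while the (delayed) |position| is below this, m.
    miskey_prob
        Per-tick probability of replacing the intended key with a uniform
        random one while attentive (motor noise).
    """

    reaction_delay: float = 0.1
    deadband: float = 0.4
    miskey_prob: float = 0.01
    lapse_schedule: LapseSchedule = field(default_factory=LapseSchedule)

    def __post_init__(self) -> None:
        if self.reaction_delay < 0 or self.deadband < 0:
            raise InvalidParameterError("delay and deadband must be non-negative")
        if not 0 <= self.miskey_prob <= 1:
            raise InvalidParameterError("miskey_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``archetype_mix`` gives the sampling proportions of the four
    archetypes; ``skill_age_slope`` scales how strongly driver skill
    improves with age (0 removes the gradient, 1 is the default)."""

    n_participants: int = 63
    age_range: tuple[int, int] = (7, 17)
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "uniform_good": 0.70,
            "uniform_poor": 0.10,
            "onset_loss": 0.10,
            "alternating": 0.10,
        }
    )
    skill_age_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise InvalidParameterError("n_participants must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise InvalidParameterError("age_range must be (min, max) with min <= max")
        mix = dict(self.archetype_mix)
        unknown = set(mix) - set(ARCHETYPES)
        if unknown:
            raise InvalidParameterError(f"unknown archetype(s): {sorted(unknown)}")
        if any(p < 0 for p in mix.values()):
            raise InvalidParameterError("archetype proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("archetype proportions must sum to 1")
        object.__setattr__(self, "archetype_mix", mix)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "age_range": list(self.age_range),
            "archetype_mix": dict(self.archetype_mix),
            "skill_age_slope": self.skill_age_slope,
            "seed": self.seed,
        }


def lapsed_policy() -> Key:
    """Key pressed while inattentive: none — the car is left to drift."""
    return "none"


def attentive_policy(
    state: CarState,
    profile: DriverProfile,
    history: Sequence[float],
    sample_rate: float = 50.0,
    rng: np.random.Generator | None = None,
) -> Key:
    """Reference implementation of the attentive controller.

    ``history`` holds observed positions, most recent last; the driver
    acts on the position ``reaction_delay`` seconds old (history shorter
    than the delay is padded with the first entry, or the current
    position if empty).  With an rng, the intended key is replaced by a
    uniform random one with probability ``miskey_prob``; exactly one
    ``random()`` and one ``integers(0, 3)`` are consumed per call.
    """
    d = int(round(profile.reaction_delay * sample_rate))
    if d == 0:
        obs = state.lateral_position
    elif len(history) >= d:
        obs = history[-d]
    elif history:
        obs = history[0]
    else:
        obs = state.lateral_position
    if obs > profile.deadband:
        key: Key = "left"
    elif obs < -profile.deadband:
        key = "right"
    else:
        key = "none"
    if rng is not None:
        u = rng.random()
        alt = int(rng.integers(0, 3))
        if u < profile.miskey_prob:
            key = str(_KEY_NAMES[alt])  # type: ignore[assignment]
    return key


def make_lapse_schedule(
    archetype: str,
    session_duration: float,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> LapseSchedule:
    """Build the lapse schedule for one archetype.

    params (all optional):
        onset_s             onset_loss: fixed onset time, s
        onset_frac_range    onset_loss: (lo, hi) fraction of the session
                            to draw the onset from (default (0.3, 0.6))
        mean_on_s           alternating: mean attentive stretch (default 120)
        mean_off_s          alternating: mean inattentive stretch (default 90)

    Alternating durations are drawn uniformly from [0.5, 1.5] x mean, so
    at the defaults a standard-length session always contains at least
    two lapse intervals.
    """
    if not session_duration > 0:
        raise InvalidParameterError("session_duration must be positive")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if archetype == "uniform_good":
        return LapseSchedule(())
    if archetype == "uniform_poor":
        return LapseSchedule(((0.0, session_duration),))
    if archetype == "onset_loss":
        if "onset_s" in params:
            onset = float(params["onset_s"])
        else:
            lo, hi = params.get("onset_frac_range", (0.3, 0.6))
            onset = float(rng.uniform(lo, hi) * session_duration)
        if not 0 <= onset < session_duration:
            raise InvalidParameterError("onset must fall inside the session")
        return LapseSchedule(((onset, session_duration),))
    if archetype == "alternating":
        mean_on = float(params.get("mean_on_s", 120.0))
        mean_off = float(params.get("mean_off_s", 90.0))
        intervals: list[tuple[float, float]] = []
        t = float(rng.uniform(0.5, 1.5) * mean_on)
        while t < session_duration:
            off = float(rng.uniform(0.5, 1.5) * mean_off)
            end = min(t + off, session_duration)
            intervals.append((t, end))
            t = end + float(rng.uniform(0.5, 1.5) * mean_on)
        return LapseSchedule(tuple(intervals))
    raise InvalidParameterError(
        f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}"
    )


def profile_for_age(
    age: float,
    skill_age_slope: float = 1.0,
    lapse_schedule: LapseSchedule | None = None,
    jitter: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DriverProfile:
    """Driver parameters for a given age.

    Skill improves linearly from age 7 to 17: reaction delay 0.14 → 0.05 s,
    deadband 0.60 → 0.30 m, motor-slip probability 0.030 → 0.004 per tick
    at slope 1.  ``jitter`` multiplies (delay, deadband, miskey) to model
    individual differences.
    """
    a = min(max((17.0 - age) / 10.0, 0.0), 1.0) * skill_age_slope
    return DriverProfile(
        reaction_delay=(0.05 + 0.09 * a) * jitter[0],
        deadband=(0.30 + 0.30 * a) * jitter[1],
        miskey_prob=min(1.0, (0.004 + 0.026 * a) * jitter[2]),
        lapse_schedule=lapse_schedule or LapseSchedule(),
    )


def simulate_session(
    track: Track,
    profile: DriverProfile,
    cfg: DynamicsConfig | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    age: int | None = None,
) -> SessionRecord:
    """Run the closed loop (policy → key → dynamics → record) for exactly
    ``cfg.samples_per_session`` ticks.

    Sample i stores the state after the step from t = i/rate: the key
    chosen at that tick, the road direction at t, the resulting clamped
    position and the collision flag.  Identical (track, profile, cfg,
    seed) produce identical records.
    """
    cfg = cfg or DynamicsConfig()
    n = cfg.samples_per_session
    dt = cfg.dt
    if track.total_duration * cfg.sample_rate < n - 1e-9:
        raise InvalidParameterError(
            f"track of {track.total_duration:.2f}s is shorter than the "
            f"{n / cfg.sample_rate:.2f}s session"
        )
    # Per-tick, precomputed: segment drift velocity, road code, lapse mask,
    # and the full random streams (see module docstring for the contract).
    t_ticks = np.arange(n) * dt
    starts = np.concatenate(([0.0], np.cumsum([s.duration for s in track.segments])))
    seg_idx = np.clip(np.searchsorted(starts, t_ticks, side="right") - 1,
                      0, len(track.segments) - 1)
    drift_signs = np.array([s.kind.drift_sign for s in track.segments])
    road_codes = np.array([s.kind.code for s in track.segments])
    drift = (drift_signs[seg_idx] * cfg.curve_drift_ratio * cfg.lateral_speed).tolist()
    roads = road_codes[seg_idx]
    lapsed = profile.lapse_schedule.tick_mask(n, cfg.sample_rate).tolist()

    rng = np.random.default_rng(seed)
    u = rng.random(n).tolist()
    alt = rng.integers(0, 3, size=n).tolist()

    d = int(round(profile.reaction_delay * cfg.sample_rate))
    deadband = profile.deadband
    miskey = profile.miskey_prob
    half = cfg.half_width
    v_key = (0.0, -cfg.lateral_speed, cfg.lateral_speed)  # none, left, right

    positions = np.empty(n)
    keys = np.empty(n, dtype=np.int8)
    collisions = np.empty(n, dtype=bool)
    states = [0.0]  # pre-step position at each tick; states[i] is pos at t=i*dt
    pos = 0.0
    for i in range(n):
        if lapsed[i]:
            k = 0
        else:
            obs = states[i - d] if i >= d else 0.0
            if obs > deadband:
                k = 1
            elif obs < -deadband:
                k = 2
            else:
                k = 0
            if u[i] < miskey:
                k = alt[i]
        pos = pos + dt * (v_key[k] + drift[i])
        col = False
        if pos > half:
            pos = half
            col = True
        elif pos < -half:
            pos = -half
            col = True
        states.append(pos)
        positions[i] = pos
        keys[i] = k
        collisions[i] = col

    return SessionRecord(
        participant_id=participant_id,
        age=age,
        sample_rate=cfg.sample_rate,
        positions=positions,
        road_directions=roads.astype("<U1"),
        keys=_KEY_NAMES[keys].astype("<U5"),
        collisions=collisions,
        config_echo={
            "dynamics": cfg.to_dict(),
            "profile": {
                "reaction_delay": profile.reaction_delay,
                "deadband": profile.deadband,
                "miskey_prob": profile.miskey_prob,
                "lapse_intervals": [list(iv) for iv in profile.lapse_schedule.intervals],
            },
            "seed": int(seed),
        },
    )


def generate_cohort(
    spec: CohortSpec,
    track: Track | None = None,
    cfg: DynamicsConfig | None = None,
) -> Cohort:
    """Generate a fully reproducible synthetic cohort.

    For participant j the master rng (seeded from ``spec.seed``) draws, in
    order: age (uniform integer over the range), archetype (from the mix),
    three skill-jitter factors (uniform [0.8, 1.2]), a lapse-schedule seed
    and a session seed.  Participant ids are ``<age>-<k>`` with k a
    per-age counter, mirroring labels like ``11-6``.
    """
    cfg = cfg or DynamicsConfig()
    track = track or default_track(spec.seed, cfg)
    rng = np.random.default_rng(spec.seed)
    names = list(ARCHETYPES)
    probs = np.array([spec.archetype_mix.get(a, 0.0) for a in names])
    sessions: list[SessionRecord] = []
    rows = []
    age_counter: dict[int, int] = {}
    for _ in range(spec.n_participants):
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        archetype = names[int(rng.choice(len(names), p=probs))]
        jitter = tuple(rng.uniform(0.8, 1.2, size=3))
        sched_seed = int(rng.integers(0, 2**31 - 1))
        sess_seed = int(rng.integers(0, 2**31 - 1))
        age_counter[age] = age_counter.get(age, 0) + 1
        pid = f"{age}-{age_counter[age]}"
        schedule = make_lapse_schedule(archetype, cfg.session_duration, seed=sched_seed)
        profile = profile_for_age(age, spec.skill_age_slope, schedule, jitter)
        sessions.append(
            simulate_session(track, profile, cfg, sess_seed, participant_id=pid, age=age)
        )
        rows.append(
            {
                "participant_id": pid,
                "age": age,
                "archetype": archetype,
                "seed": sess_seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["participant_id", "age", "archetype", "seed"]
    )
    return Cohort(sessions=sessions, manifest=manifest)


def generate_archetype_group(
    counts: Mapping[str, int],
    age: int,
    seed: int = 0,
    cfg: DynamicsConfig | None = None,
    track: Track | None = None,
    params: Mapping[str, float] | None = None,
    skill_age_slope: float = 1.0,
) -> Cohort:
    """Generate a single-age group with fixed archetype counts.

    Used for planted-structure experiments (cluster-count recovery,
    lapse-onset recovery) where the archetype of every participant must
    be controlled exactly.  ``params`` is passed to
    :func:`make_lapse_schedule` (e.g. a fixed ``onset_s``).
    """
    cfg = cfg or DynamicsConfig()
    track = track or default_track(seed, cfg)
    unknown = set(counts) - set(ARCHETYPES)
    if unknown:
        raise InvalidParameterError(f"unknown archetype(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sessions = []
    rows = []
    k = 0
    for archetype in ARCHETYPES:
        for _ in range(int(counts.get(archetype, 0))):
            k += 1
            pid = f"{age}-{k}"
            jitter = tuple(rng.uniform(0.8, 1.2, size=3))
            sched_seed = int(rng.integers(0, 2**31 - 1))
            sess_seed = int(rng.integers(0, 2**31 - 1))
            schedule = make_lapse_schedule(
                archetype, cfg.session_duration, params=params, seed=sched_seed
            )
            profile = profile_for_age(age, skill_age_slope, schedule, jitter)
            sessions.append(
                simulate_session(
                    track, profile, cfg, sess_seed, participant_id=pid, age=age
                )
            )
            rows.append({"participant_id": pid, "age": age, "archetype": archetype,
                         "seed": sess_seed})
    manifest = pd.DataFrame(rows, columns=["participant_id", "age", "archetype", "seed"])
    return Cohort(sessions=sessions, manifest=manifest)
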