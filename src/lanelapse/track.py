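"""Virtual circuit and 1-D lateral car dynamics.

The driving task records only the car's signed lateral offset from the road
centerline, so the track is modelled as an ordered sequence of timed
segments (straight, left curve, right curve) and the car as a single
clamped scalar state.  The kinematics are deliberately simple: arrow keys
move the car laterally at a fixed speed, curves push it toward the outside
at a fixed fraction of that speed, and the car can never leave the road —
it rides the edge instead, raising a collision flag.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InvalidParameterError, OutOfRangeError

Key = Literal["left", "right", "none"]

#: Number of curves / straights on the default test circuit.
DEFAULT_N_CURVES = 58
DEFAULT_N_STRAIGHTS = 58


class SegmentKind(str, Enum):
    STRAIGHT = "straight"
    LEFT_CURVE = "left_curve"
    RIGHT_CURVE = "right_curve"

    @property
    def code(self) -> str:
        """Single-letter code used in session files: S, L or R."""
        return {"straight": "S", "left_curve": "L", "right_curve": "R"}[self.value]

    @property
    def drift_sign(self) -> int:
        """Sign of the outward drift: +1 on a left curve (outside is the
        right), -1 on a right curve, 0 on a straight."""
        return {"straight": 0, "left_curve": 1, "right_curve": -1}[self.value]


@dataclass(frozen=True)
class TrackSegment:
    """One timed stretch of road."""

    kind: SegmentKind
    duration: float  # seconds

    def __post_init__(self) -> None:
        if not isinstance(self.kind, SegmentKind):
            object.__setattr__(self, "kind", SegmentKind(self.kind))
        if not self.duration > 0:
            raise InvalidParameterError(
                f"segment duration must be positive, got {self.duration!r}"
            )


@dataclass(frozen=True)
class Track:
    """An ordered circuit of segments."""

    segments: tuple[TrackSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @cached_property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @cached_property
    def _starts(self) -> list[float]:
        starts, acc = [], 0.0
        for s in self.segments:
            starts.append(acc)
            acc += s.duration
        return starts

    def __len__(self) -> int:
        return len(self.segments)

    def count(self, kind: SegmentKind) -> int:
        return sum(1 for s in self.segments if s.kind is kind)

    @property
    def n_curves(self) -> int:
        """Left and right curves pooled."""
        return self.count(SegmentKind.LEFT_CURVE) + self.count(SegmentKind.RIGHT_CURVE)

    @property
    def n_straights(self) -> int:
        return self.count(SegmentKind.STRAIGHT)


@dataclass(frozen=True)
class CarState:
    """Lateral car state at one instant.

    ``lateral_position`` is signed: 0 is the centerline, positive is to the
    right.  ``collided`` records whether the clamp at the road edge was
    engaged during the last step.
    """

    t: float
    lateral_position: float
    collided: bool = False


@dataclass(frozen=True)
class DynamicsConfig:
    """Task constants.

    lateral_speed
        Speed of the key-commanded lateral movement, m/s.
    curve_drift_ratio
        Outward drift on curves as a fraction of ``lateral_speed``.
    half_width
        Half the road width, m; positions are clamped to ±half_width.
    sample_rate
        Recording frequency, Hz.
    samples_per_session
        Fixed number of recorded samples per session, so every
        participant's series has identical length.
    """

    lateral_speed: float = 10.0
    curve_drift_ratio: float = 0.45
    half_width: float = 3.0
    sample_rate: float = 50.0
    samples_per_session: int = 34_496

    def __post_init__(self) -> None:
        if not self.lateral_speed > 0:
            raise InvalidParameterError("lateral_speed must be > 0")
        if not 0 <= self.curve_drift_ratio < 1:
            raise InvalidParameterError("curve_drift_ratio must be in [0, 1)")
        if not self.half_width > 0:
            raise InvalidParameterError("half_width must be > 0")
        if not self.sample_rate > 0:
            raise InvalidParameterError("sample_rate must be > 0")
        if not self.samples_per_session > 0:
            raise InvalidParameterError("samples_per_session must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def session_duration(self) -> float:
        """Recorded session length in seconds."""
        return self.samples_per_session / self.sample_rate

    def to_dict(self) -> dict:
        return {
            "lateral_speed": self.lateral_speed,
            "curve_drift_ratio": self.curve_drift_ratio,
            "half_width": self.half_width,
            "sample_rate": self.sample_rate,
            "samples_per_session": self.samples_per_session,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicsConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


def default_segment_duration(cfg: DynamicsConfig | None = None) -> float:
    """Segment duration that tiles the default 116-segment circuit with
    exactly ``samples_per_session`` samples (~5.9476 s at the defaults)."""
    cfg = cfg or DynamicsConfig()
    n_segments = DEFAULT_N_CURVES + DEFAULT_N_STRAIGHTS
    return cfg.session_duration / n_segments


def build_track(
    n_curves: int,
    n_straights: int,
    segment_duration: float,
    curve_direction_seed: int = 0,
) -> Track:
    """Build a circuit alternating straight → curve (starting with a
    straight) until one kind runs out, then appending the remainder.

    Curve handedness is drawn 50/50 left/right from
    ``curve_direction_seed`` so the signed-position analysis sees both
    drift signs reproducibly.
    """
    if n_curves < 0 or n_straights < 0:
        raise InvalidParameterError("segment counts must be non-negative")
    if (n_curves or n_straights) and not segment_duration > 0:
        raise InvalidParameterError("segment_duration must be positive")
    rng = np.random.default_rng(curve_direction_seed)
    kinds: list[SegmentKind] = []
    c, s = n_curves, n_straights
    while c > 0 or s > 0:
        if s > 0:
            kinds.append(SegmentKind.STRAIGHT)
            s -= 1
        if c > 0:
            kinds.append(
                SegmentKind.LEFT_CURVE if rng.random() < 0.5 else SegmentKind.RIGHT_CURVE
            )
            c -= 1
    return Track(tuple(TrackSegment(k, segment_duration) for k in kinds))


def default_track(seed: int = 0, cfg: DynamicsConfig | None = None) -> Track:
    """The 58-curve / 58-straight test circuit sized so the default session
    sample count tiles it exactly."""
    return build_track(
        DEFAULT_N_CURVES, DEFAULT_N_STRAIGHTS, default_segment_duration(cfg), seed
    )


def tutorial_track(seed: int = 0) -> Track:
    """The 40-second practice circuit: 4 curves and 4 straights of 5 s."""
    return build_track(4, 4, 5.0, seed)


def segment_at(track: Track, t: float) -> TrackSegment:
    """Segment whose half-open interval [start, start + duration) holds t."""
    if not 0 <= t < track.total_duration:
        raise OutOfRangeError(
            f"t={t!r} outside [0, {track.total_duration!r})"
        )
    i = bisect.bisect_right(track._starts, t) - 1
    return track.segments[i]


def step_dynamics(
    state: CarState,
    segment: TrackSegment,
    key: Key,
    dt: float,
    cfg: DynamicsConfig,
) -> CarState:
    """Advance the lateral state by one explicit-Euler step.

    The new position is ``old + dt * (key_velocity + drift_velocity)``,
    clamped to the road; the collision flag is set exactly when the clamp
    changed the value.
    """
    if not dt > 0:
        raise InvalidParameterError("dt must be positive")
    if key == "left":
        v_key = -cfg.lateral_speed
    elif key == "right":
        v_key = cfg.lateral_speed
    elif key == "none":
        v_key = 0.0
    else:
        raise InvalidParameterError(f"unknown key {key!r}")
    v_drift = segment.kind.drift_sign * cfg.curve_drift_ratio * cfg.lateral_speed
    unclamped = state.lateral_position + dt * (v_key + v_drift)
    clamped = min(max(unclamped, -cfg.half_width), cfg.half_width)
    return CarState(
        t=state.t + dt,
        lateral_position=clamped,
        collided=clamped != unclamped,
    )


def track_to_json(track: Track, *, seed: int | None = None,
                  config: DynamicsConfig | None = None) -> str:
    """Serialize a track (with optional provenance) to a JSON string."""
    doc = {
        "segments": [
            {"kind": s.kind.value, "duration": s.duration} for s in track.segments
        ],
        "metadata": {
            "seed": seed,
            "config": config.to_dict() if config is not None else None,
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def track_from_json(text: str) -> Track:
    doc = json.loads(text)
    return Track(
        tuple(
            TrackSegment(SegmentKind(s["kind"]), float(s["duration"]))
            for s in doc["segments"]
        )
    )
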