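"""Attention loss/recovery localization from sustained out-of-fence error.

The procedure, applied per participant:

1. pool the *signed* positions of every participant of the same age and
   compute Tukey fences on them (the participant under analysis is
   included by default; a leave-one-out flag exists for sensitivity
   analysis);
2. mark each of the participant's samples as outlying when its position
   falls strictly outside the fences;
3. keep only *sustained* runs of consecutive outlying samples lasting at
   least ``min_duration`` (default 1 s, i.e. 50 samples at 50 Hz,
   inclusive) — isolated atypical instants are discarded;
4. summarize the runs into an attention profile: time of first loss,
   total inattentive time, and whether attention was held to the end.

Run boundaries are half-open sample-index intervals [start, end): ``end``
is the first non-outlying index after the run, so "attention recovered
from observation e" reads directly off the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .error_stats import boxplot_stats, age_grouped_positions
from .errors import InvalidParameterError, ParticipantNotFoundError
from .session_io import Cohort, SessionRecord


@dataclass(frozen=True)
class OutlierMask:
    participant_id: str
    mask: np.ndarray  # bool per sample
    fences_used: tuple[float, float]
    sample_rate: float = 50.0

    def __len__(self) -> int:
        return len(self.mask)


@dataclass(frozen=True)
class SustainedRun:
    """Maximal stretch of consecutive outlying samples, [start, end)."""

    start_index: int
    end_index: int
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise InvalidParameterError("run must satisfy 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def start_minutes(self) -> float:
        return index_to_minutes(self.start_index, self.sample_rate)

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class AttentionProfile:
    participant_id: str
    runs: tuple[SustainedRun, ...]
    first_loss_minutes: float | None
    total_inattentive_seconds: float
    attentive_to_end: bool
    fences_used: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "fences": list(self.fences_used) if self.fences_used else None,
            "runs": [
                {
                    "start_index": r.start_index,
                    "end_index": r.end_index,
                    "start_minutes": round(r.start_minutes, 2),
                    "duration_seconds": round(r.duration_seconds, 2),
                }
                for r in self.runs
            ],
            "first_loss_minutes": (
                None if self.first_loss_minutes is None
                else round(self.first_loss_minutes, 2)
            ),
            "total_inattentive_seconds": round(self.total_inattentive_seconds, 2),
            "attentive_to_end": self.attentive_to_end,
        }


def index_to_minutes(index: int, sample_rate: float) -> float:
    """Convert a sample index to minutes from task start."""
    if index < 0:
        raise InvalidParameterError("index must be non-negative")
    if not sample_rate > 0:
        raise InvalidParameterError("sample_rate must be positive")
    return index / sample_rate / 60.0


def outlier_mask(
    session: SessionRecord, fences: tuple[float, float]
) -> OutlierMask:
    """Per-sample outlier flags against a fence interval.

    A sample is outlying when its signed position is strictly below the
    lower fence or strictly above the upper one; boundary values are not
    outlying.  Equal fences (a degenerate zero-IQR group) are allowed and
    flagged with a warning: every deviation from the common value is then
    an outlier.
    """
    lower, upper = float(fences[0]), float(fences[1])
    if lower > upper:
        raise InvalidParameterError(f"fences must satisfy lower <= upper, got {fences}")
    if lower == upper:
        warnings.warn(
            "degenerate fences (lower == upper): every deviation is an outlier",
            stacklevel=2,
        )
    pos = np.asarray(session.positions, dtype=float)
    mask = (pos < lower) | (pos > upper)
    return OutlierMask(
        participant_id=session.participant_id,
        mask=mask,
        fences_used=(lower, upper),
        sample_rate=session.sample_rate,
    )


def sustained_runs(
    mask: OutlierMask | np.ndarray,
    min_duration: float = 1.0,
    sample_rate: float | None = None,
) -> list[SustainedRun]:
    """Maximal runs of consecutive outlying samples lasting at least
    ``min_duration`` seconds (inclusive); shorter runs are discarded."""
    if not min_duration > 0:
        raise InvalidParameterError("min_duration must be positive")
    if isinstance(mask, OutlierMask):
        rate = sample_rate if sample_rate is not None else mask.sample_rate
        m = np.asarray(mask.mask, dtype=bool)
    else:
        if sample_rate is None:
            raise InvalidParameterError("sample_rate required with a bare mask array")
        rate = sample_rate
        m = np.asarray(mask, dtype=bool)
    min_samples = int(np.ceil(min_duration * rate - 1e-9))
    if m.size == 0:
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    return [
        SustainedRun(int(s), int(e), rate)
        for s, e in zip(starts, ends)
        if e - s >= min_samples
    ]


def attention_profile(
    runs: list[SustainedRun],
    session_length: int,
    sample_rate: float,
    participant_id: str = "",
    fences: tuple[float, float] | None = None,
) -> AttentionProfile:
    """Summarize sustained runs into an attention timeline."""
    runs = sorted(runs, key=lambda r: r.start_index)
    first_loss = index_to_minutes(runs[0].start_index, sample_rate) if runs else None
    total = sum(r.duration_seconds for r in runs)
    touches_end = bool(runs) and runs[-1].end_index >= session_length
    return AttentionProfile(
        participant_id=participant_id,
        runs=tuple(runs),
        first_loss_minutes=first_loss,
        total_inattentive_seconds=float(total),
        attentive_to_end=not touches_end,
        fences_used=fences,
    )


def group_fences(
    cohort: Cohort,
    age: int,
    leave_out: str | None = None,
) -> tuple[float, float]:
    """Tukey fences on the pooled signed positions of an age group.

    ``leave_out`` excludes one participant from the pool (sensitivity
    analysis); by default the analyzed participant is included.
    """
    if leave_out is None:
        pooled = age_grouped_positions(cohort, age, signed=True)
    else:
        sessions = [
            s for s in cohort.by_age(age) if s.participant_id != leave_out
        ]
        if not sessions:
            raise InvalidParameterError(
                f"age group {age} has no other participants to pool"
            )
        pooled = np.concatenate([np.asarray(s.positions, float) for s in sessions])
    st = boxplot_stats(pooled)
    if st.iqr == 0:
        warnings.warn(
            f"age group {age} has zero IQR; fences collapse to a point",
            stacklevel=2,
        )
    return (st.lower_fence, st.upper_fence)


def compute_attention(
    cohort: Cohort,
    participant_id: str,
    min_duration_s: float = 1.0,
    leave_one_out: bool = False,
) -> AttentionProfile:
    """Full pipeline: age-group fences → outlier mask → sustained runs →
    attention profile, for one participant."""
    session = cohort.get(participant_id)  # raises ParticipantNotFoundError
    if session.age is None:
        raise InvalidParameterError(
            f"participant {participant_id!r} has no age; fences are age-referenced"
        )
    fences = group_fences(
        cohort, int(session.age),
        leave_out=participant_id if leave_one_out else None,
    )
    mask = outlier_mask(session, fences)
    runs = sustained_runs(mask, min_duration=min_duration_s)
    return attention_profile(
        runs, session.n_samples, session.sample_rate,
        participant_id=participant_id, fences=fences,
    )
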