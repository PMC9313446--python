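"""Driving-error metric and age-stratified boxplot statistics.

The error at each instant is the distance from the car to the road
centerline, i.e. the absolute lateral position; age groups are described
with standard boxplot statistics: quartiles, IQR and the Tukey fences
Q1 - 1.5*IQR and Q3 + 1.5*IQR, with observations strictly outside the
fences counted as outliers.

Quartiles use linear interpolation between order statistics (numpy's
default, quantile "type 7").  The convention is unambiguous and recorded
in exported tables because the fences — and therefore every downstream
attention call — depend on it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .errors import EmptyGroupError, InvalidParameterError
from .session_io import Cohort, SessionRecord

QUANTILE_METHOD = "linear"  # numpy interpolation name for quantile type 7


@dataclass(frozen=True)
class ErrorSeries:
    """Per-sample absolute error for one participant."""

    participant_id: str
    values: np.ndarray  # |position|, meters, one per sample
    sample_rate: float


@dataclass(frozen=True)
class BoxplotStats:
    q1: float
    median: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outlier_count: int
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def error_series(session: SessionRecord) -> ErrorSeries:
    """Absolute lateral error, one value per sample."""
    return ErrorSeries(
        participant_id=session.participant_id,
        values=np.abs(np.asarray(session.positions, dtype=float)),
        sample_rate=session.sample_rate,
    )


def boxplot_stats(values) -> BoxplotStats:
    """Quartiles, IQR, Tukey fences and outlier count for a collection.

    Outliers are values strictly below ``q1 - 1.5*iqr`` or strictly above
    ``q3 + 1.5*iqr``; values exactly on a fence are not outlying.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise InvalidParameterError("boxplot_stats requires at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    outliers = int(np.count_nonzero((v < lower) | (v > upper)))
    return BoxplotStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lower),
        upper_fence=float(upper),
        outlier_count=outliers,
        n=int(v.size),
    )


def age_grouped_positions(cohort: Cohort, age: int, signed: bool = False) -> np.ndarray:
    """All samples' positions pooled across participants of exactly ``age``.

    ``signed=True`` keeps the sign (used for attention fences);
    ``signed=False`` returns absolute error (used for the age boxplots).
    """
    sessions = cohort.by_age(age)
    if not sessions:
        raise EmptyGroupError(f"no participants of age {age}")
    pooled = np.concatenate([np.asarray(s.positions, dtype=float) for s in sessions])
    return pooled if signed else np.abs(pooled)


def age_boxplot_table(cohort: Cohort, signed: bool = False) -> dict[int, BoxplotStats]:
    """One :class:`BoxplotStats` per age present, on pooled errors."""
    if len(cohort) == 0:
        raise EmptyGroupError("cohort is empty")
    return {
        age: boxplot_stats(age_grouped_positions(cohort, age, signed=signed))
        for age in cohort.ages()
    }


def age_boxplot_frame(table: dict[int, BoxplotStats]) -> pd.DataFrame:
    """Tabular (CSV-exportable) view of an age boxplot table."""
    rows = [{"age": age, **st.to_dict()} for age, st in sorted(table.items())]
    frame = pd.DataFrame(
        rows,
        columns=["age", "n", "q1", "median", "q3", "iqr",
                 "lower_fence", "upper_fence", "outlier_count"],
    )
    frame.attrs["quantile_method"] = QUANTILE_METHOD
    return frame


def participant_median_errors(cohort: Cohort) -> pd.DataFrame:
    """Per-participant median absolute error with age, one row each."""
    rows = [
        {
            "participant_id": s.participant_id,
            "age": s.age,
            "median_abs_error": float(np.median(np.abs(s.positions))),
        }
        for s in cohort.sessions
    ]
    return pd.DataFrame(rows, columns=["participant_id", "age", "median_abs_error"])


def age_error_spearman(cohort: Cohort) -> float:
    """Spearman correlation between age and per-participant median
    absolute error; negative when older participants drive better."""
    frame = participant_median_errors(cohort)
    if len(frame) < 2:
        raise EmptyGroupError("need at least two participants")
    rho, _ = _scipy_stats.spearmanr(frame["age"], frame["median_abs_error"])
    return float(rho)
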