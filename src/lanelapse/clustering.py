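"""K-means clustering of error trajectories with scree-based k selection.

Participants of one age are represented by their error trajectory binned
into 10-second means (68 features for a standard-length session), which
keeps the temporal patterns that distinguish the behavioral archetypes
while avoiding distances on tens of thousands of raw samples.  K-means
(k-means++ seeding, best of several restarts) is fit for k = 1..k_max;
the scree of within-cluster inertias is guaranteed non-increasing by a
nested initialization (the k-cluster fit is also started from the
(k-1)-cluster centers plus the point farthest from its center).  The
number of clusters is the interior k maximizing the second difference of
the scree — the testable surrogate for reading the elbow by eye — with
ties broken toward fewer clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .error_stats import error_series
from .errors import EmptyGroupError, InvalidParameterError
from .session_io import Cohort


@dataclass(frozen=True)
class FeatureMatrix:
    """Participants x time-bins matrix of mean absolute errors, meters."""

    participant_ids: tuple[str, ...]
    X: np.ndarray
    bin_width: float  # seconds

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != len(self.participant_ids):
            raise InvalidParameterError("X must be (participants x features)")


@dataclass(frozen=True)
class ClusterResult:
    k_values: tuple[int, ...]
    inertias: tuple[float, ...]
    selected_k: int
    assignments: dict[str, int]
    seed: int
    singletons: tuple[str, ...] = ()   # participant ids alone in a cluster
    no_structure: bool = False         # all trajectories (near-)identical

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "inertia": self.inertias})

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": list(self.assignments),
                "cluster": list(self.assignments.values()),
            }
        )


def feature_matrix(
    cohort: Cohort, age: int, bin_width: float = 10.0
) -> FeatureMatrix:
    """Binned mean-absolute-error features for one age group.

    Column j is the mean absolute error over time bin j; the trailing
    partial bin is dropped, so a 689.92 s session at 10 s bins yields 68
    features.
    """
    if not bin_width > 0:
        raise InvalidParameterError("bin_width must be positive")
    sessions = cohort.by_age(age)
    if not sessions:
        raise EmptyGroupError(f"no participants of age {age}")
    rows, ids = [], []
    for s in sessions:
        es = error_series(s)
        per_bin = int(bin_width * es.sample_rate)
        if per_bin < 1 or len(es.values) < per_bin:
            raise InvalidParameterError("bin_width too large for the session")
        n_bins = len(es.values) // per_bin
        rows.append(
            es.values[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
        )
        ids.append(s.participant_id)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise InvalidParameterError("sessions of one age group differ in length")
    return FeatureMatrix(tuple(ids), np.vstack(rows), bin_width)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.X, dtype=float)
    return np.asarray(X, dtype=float)


def _fit(X: np.ndarray, k: int, init, n_init: int, seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, init=init, n_init=n_init,
                    random_state=seed % (2**31)).fit(X)
    return km.labels_.astype(int), float(km.inertia_), km.cluster_centers_


def kmeans_fit(
    X, k: int, seed: int = 0, restarts: int = 10
) -> tuple[np.ndarray, float]:
    """Best-of-restarts k-means: returns (labels, inertia)."""
    M = _as_matrix(X)
    n = M.shape[0]
    if not 1 <= k <= n:
        raise InvalidParameterError(f"k={k} must be in [1, {n}]")
    labels, inertia, _ = _fit(M, k, "k-means++", restarts, seed)
    return labels, inertia


def _scree_with_labels(
    M: np.ndarray, k_max: int, seed: int, restarts: int
) -> tuple[list[tuple[int, float]], dict[int, np.ndarray]]:
    out: list[tuple[int, float]] = []
    labels_by_k: dict[int, np.ndarray] = {}
    prev_centers: np.ndarray | None = None
    prev_inertia = np.inf
    for k in range(1, k_max + 1):
        labels, inertia, centers = _fit(M, k, "k-means++", restarts, seed + k)
        if prev_centers is not None:
            # nested init: previous centers plus the worst-fit point; its
            # starting inertia is <= W(k-1), so the scree cannot rise
            d2 = ((M[:, None, :] - prev_centers[None, :, :]) ** 2).sum(-1).min(1)
            split = M[int(np.argmax(d2))]
            init = np.vstack([prev_centers, split])
            labels2, inertia2, centers2 = _fit(M, k, init, 1, seed + k)
            if inertia2 < inertia:
                labels, inertia, centers = labels2, inertia2, centers2
        inertia = min(inertia, prev_inertia)  # float-noise guard
        out.append((k, inertia))
        labels_by_k[k] = labels
        prev_centers, prev_inertia = centers, inertia
    return out, labels_by_k


def scree(
    X, k_max: int, seed: int = 0, restarts: int = 10
) -> list[tuple[int, float]]:
    """Within-cluster inertia for k = 1..k_max (non-increasing)."""
    M = _as_matrix(X)
    n = M.shape[0]
    if not 1 <= k_max <= n:
        raise InvalidParameterError(f"k_max={k_max} must be in [1, {n}]")
    entries, _ = _scree_with_labels(M, k_max, seed, restarts)
    return entries


def select_k(inertias: Sequence[tuple[int, float]]) -> int:
    """Elbow rule: the interior k maximizing
    (W(k-1) - W(k)) - (W(k) - W(k+1)), ties broken toward smaller k."""
    if len(inertias) < 3:
        raise InvalidParameterError("need inertias for at least three k values")
    ks = [k for k, _ in inertias]
    ws = [w for _, w in inertias]
    best_k, best_score = None, -np.inf
    for i in range(1, len(ks) - 1):
        score = ws[i - 1] - 2 * ws[i] + ws[i + 1]
        if score > best_score:
            best_k, best_score = ks[i], score
    return int(best_k)


def cluster_age_group(
    cohort: Cohort,
    age: int,
    k_max: int = 6,
    seed: int = 0,
    bin_width: float = 10.0,
    restarts: int = 10,
) -> ClusterResult:
    """Full clustering pipeline for one age group.

    feature_matrix → scree → select_k → final assignment; singleton
    clusters (a child behaving unlike everyone else) are reported by
    member id, and a near-zero total inertia is flagged as
    ``no_structure``.
    """
    fm = feature_matrix(cohort, age, bin_width)
    n = fm.X.shape[0]
    if n < 2:
        raise InvalidParameterError("clustering needs at least two participants")
    k_hi = min(k_max, n)
    entries, labels_by_k = _scree_with_labels(
        _as_matrix(fm), k_hi, seed, restarts
    )
    if len(entries) >= 3:
        selected = select_k(entries)
    else:
        selected = k_hi
    labels = labels_by_k[selected]
    total_inertia = entries[0][1]
    scale = float(np.abs(fm.X).max()) or 1.0
    no_structure = total_inertia <= 1e-9 * scale**2 * fm.X.size
    assignments = {pid: int(lbl) for pid, lbl in zip(fm.participant_ids, labels)}
    counts = np.bincount(labels, minlength=selected)
    singletons = tuple(
        pid for pid, lbl in assignments.items() if counts[lbl] == 1
    )
    return ClusterResult(
        k_values=tuple(k for k, _ in entries),
        inertias=tuple(w for _, w in entries),
        selected_k=selected,
        assignments=assignments,
        seed=seed,
        singletons=singletons,
        no_structure=bool(no_structure),
    )
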