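"""Readers and writers for session recordings and cohort manifests.

A session is stored as a plain CSV with ``#``-prefixed metadata comment
lines so it stays loadable by any generic CSV tool:

    # participant_id: 11-6
    # age: 11
    # sample_rate: 50
    # config: {"half_width": 3.0, ...}
    index,t,position,road_direction,key,collision
    0,0.000000,0.013500,L,none,0

Positions and times are printed with a fixed 6-decimal format, which makes
write → read → write byte-identical and exceeds every analysis tolerance.
A cohort is a manifest CSV (participant_id, age, session_file, optional
archetype/seed) with session files resolved relative to the manifest.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParticipantNotFoundError, SessionFormatError

logger = logging.getLogger(__name__)

ROAD_DIRECTIONS = ("S", "L", "R")
KEYS = ("none", "left", "right")

_REQUIRED_COLUMNS = ["index", "t", "position", "road_direction", "key", "collision"]
_MANIFEST_COLUMNS = ["participant_id", "age", "session_file"]


@dataclass(frozen=True)
class Sample:
    """One 50 Hz recording row."""

    index: int
    t: float
    position: float
    road_direction: str  # S / L / R
    key: str             # left / right / none
    collision: bool


@dataclass
class SessionRecord:
    """One participant's full recording.

    Column arrays are stored directly (rather than a list of Sample
    objects) so a 34,496-row session stays cheap to analyse; ``samples()``
    yields :class:`Sample` rows for code that wants the record view.
    """

    participant_id: str
    age: int | None
    sample_rate: float
    positions: np.ndarray          # float, signed meters
    road_directions: np.ndarray    # '<U1', S/L/R
    keys: np.ndarray               # '<U5', left/right/none
    collisions: np.ndarray         # bool
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name in ("road_directions", "keys", "collisions"):
            if len(getattr(self, name)) != n:
                raise SessionFormatError(f"column {name!r} has mismatched length")

    @property
    def n_samples(self) -> int:
        return len(self.positions)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def samples(self) -> Iterator[Sample]:
        for i in range(self.n_samples):
            yield Sample(
                index=i,
                t=i / self.sample_rate,
                position=float(self.positions[i]),
                road_direction=str(self.road_directions[i]),
                key=str(self.keys[i]),
                collision=bool(self.collisions[i]),
            )


@dataclass
class Cohort:
    """A set of sessions plus per-participant metadata."""

    sessions: list[SessionRecord]
    manifest: pd.DataFrame  # participant_id, age, plus optional columns

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SessionFormatError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.sessions]

    def get(self, participant_id: str) -> SessionRecord:
        for s in self.sessions:
            if s.participant_id == participant_id:
                return s
        raise ParticipantNotFoundError(participant_id)

    def ages(self) -> list[int]:
        return sorted({int(s.age) for s in self.sessions if s.age is not None})

    def by_age(self, age: int) -> list[SessionRecord]:
        return [s for s in self.sessions if s.age is not None and int(s.age) == age]


def write_session(record: SessionRecord, path: str | Path) -> Path:
    """Write a session CSV (dialect in the module docstring)."""
    path = Path(path)
    config_json = json.dumps(record.config_echo, sort_keys=True, separators=(",", ":"))
    n = record.n_samples
    buf = io.StringIO()
    buf.write(f"# participant_id: {record.participant_id}\n")
    buf.write(f"# age: {'' if record.age is None else int(record.age)}\n")
    buf.write(f"# sample_rate: {record.sample_rate:g}\n")
    buf.write(f"# config: {config_json}\n")
    frame = pd.DataFrame(
        {
            "index": np.arange(n, dtype=np.int64),
            "t": np.arange(n) / record.sample_rate,
            "position": record.positions,
            "road_direction": record.road_directions,
            "key": record.keys,
            "collision": record.collisions.astype(np.int64),
        }
    )
    frame.to_csv(buf, index=False, float_format="%.6f", lineterminator="\n")
    path.write_text(buf.getvalue())
    return path


def _parse_comment_header(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        k, v = body.split(":", 1)
        meta[k.strip()] = v.strip()
    return meta


def read_session(path: str | Path) -> SessionRecord:
    """Read a session CSV, validating the on-disk contract.

    Unknown columns are ignored with a logged warning; a missing required
    column or a gap in the index column is a :class:`SessionFormatError`.
    """
    path = Path(path)
    comments: list[str] = []
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                comments.append(line)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh)
    meta = _parse_comment_header(comments)

    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"missing required column(s): {missing}")
    extra = [c for c in frame.columns if c not in _REQUIRED_COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s) %s in %s", extra, path)

    idx = frame["index"].to_numpy()
    expected = np.arange(len(idx))
    if len(idx) and not np.array_equal(idx, expected):
        gap = int(np.argmax(idx != expected))
        raise SessionFormatError(
            f"non-contiguous sample indices: first gap after row {gap - 1} "
            f"(found index {idx[gap]}, expected {gap})"
        )

    sample_rate = float(meta.get("sample_rate", 50.0))
    t = frame["t"].to_numpy(dtype=float)
    if len(t) and np.max(np.abs(t - expected / sample_rate)) > 1e-6:
        raise SessionFormatError("t column inconsistent with index / sample_rate")

    bad_dir = set(frame["road_direction"].unique()) - set(ROAD_DIRECTIONS)
    if bad_dir:
        raise SessionFormatError(f"unknown road_direction value(s): {sorted(bad_dir)}")
    bad_key = set(frame["key"].unique()) - set(KEYS)
    if bad_key:
        raise SessionFormatError(f"unknown key value(s): {sorted(bad_key)}")

    age_raw = meta.get("age", "")
    config_raw = meta.get("config", "{}")
    try:
        config_echo = json.loads(config_raw)
    except json.JSONDecodeError:
        config_echo = {}
    return SessionRecord(
        participant_id=meta.get("participant_id", path.stem),
        age=int(age_raw) if age_raw else None,
        sample_rate=sample_rate,
        positions=frame["position"].to_numpy(dtype=float),
        road_directions=frame["road_direction"].to_numpy(dtype="<U1"),
        keys=frame["key"].to_numpy(dtype="<U5"),
        collisions=frame["collision"].to_numpy().astype(bool),
        config_echo=config_echo,
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write one session CSV per participant plus ``manifest.csv``.

    Returns the manifest path.  Session files are named
    ``session_<participant_id>.csv`` and referenced relative to the
    manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for session in cohort.sessions:
        fname = f"session_{session.participant_id}.csv"
        write_session(session, directory / fname)
        row = {
            "participant_id": session.participant_id,
            "age": session.age,
            "session_file": fname,
        }
        if not cohort.manifest.empty:
            meta = cohort.manifest.set_index("participant_id")
            for col in meta.columns:
                if col not in row and session.participant_id in meta.index:
                    row[col] = meta.loc[session.participant_id, col]
        rows.append(row)
    manifest_path = directory / "manifest.csv"
    columns = _MANIFEST_COLUMNS + [
        c for c in (rows[0].keys() if rows else []) if c not in _MANIFEST_COLUMNS
    ]
    pd.DataFrame(rows, columns=columns if rows else _MANIFEST_COLUMNS).to_csv(
        manifest_path, index=False
    )
    return manifest_path


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Read a cohort from its manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SessionFormatError(f"manifest missing column(s): {missing}")
    ids = manifest["participant_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise SessionFormatError(f"duplicate participant ids in manifest: {dupes}")
    sessions = []
    for _, row in manifest.iterrows():
        session_path = manifest_path.parent / str(row["session_file"])
        if not session_path.exists():
            raise FileNotFoundError(
                f"session file {session_path} referenced by manifest does not exist"
            )
        session = read_session(session_path)
        session.participant_id = str(row["participant_id"])
        if not pd.isna(row["age"]):
            session.age = int(row["age"])
        sessions.append(session)
    return Cohort(sessions=sessions, manifest=manifest)
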