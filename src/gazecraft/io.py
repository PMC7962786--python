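"""Sample containers, CSV/ASC readers and writers, and 2 kHz -> 1 kHz decimation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GazeSample",
    "Samples",
    "TrialRecord",
    "read_samples",
    "write_samples",
    "read_trials",
    "write_trials",
    "downsample_2k_to_1k",
]

GROUPS = ("expert", "nonexpert")
TASKS = ("movement", "date", "medium")

SAMPLE_COLUMNS = ["trial_id", "t_ms", "x_px", "y_px", "valid"]
TRIAL_COLUMNS = [
    "trial_id",
    "subject_id",
    "group",
    "image_id",
    "task",
    "presentation_ms",
    "answer",
    "correct",
    "confidence_raw",
    "familiarity_raw",
]


class GazeSample(NamedTuple):
    """A single gaze sample in screen coordinates."""

    t_ms: float
    x_px: float
    y_px: float
    valid: bool


@dataclass
class Samples:
    """Column-oriented gaze samples for one trial.

    ``valid`` is False during blinks / track loss; positions of invalid
    samples are retained as recorded (possibly NaN) and never dropped.
    """

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("sample columns must have equal length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("sample timestamps must be strictly increasing within a trial")

    def __len__(self) -> int:
        return len(self.t_ms)

    def __getitem__(self, i: int) -> GazeSample:
        return GazeSample(float(self.t_ms[i]), float(self.x_px[i]), float(self.y_px[i]), bool(self.valid[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @classmethod
    def from_records(cls, records: Iterable[GazeSample]) -> "Samples":
        recs = list(records)
        return cls(
            t_ms=np.array([r.t_ms for r in recs], dtype=float),
            x_px=np.array([r.x_px for r in recs], dtype=float),
            y_px=np.array([r.y_px for r in recs], dtype=float),
            valid=np.array([r.valid for r in recs], dtype=bool),
        )

    @property
    def duration_ms(self) -> float:
        if len(self) < 2:
            return 0.0
        dt = float(np.median(np.diff(self.t_ms)))
        return float(self.t_ms[-1] - self.t_ms[0] + dt)


@dataclass
class TrialRecord:
    """One experimental trial: design cell, behavioral response and raw samples."""

    trial_id: str
    subject_id: str
    group: str
    image_id: str
    task: str
    presentation_ms: float
    answer: str
    correct: bool
    confidence_raw: int
    familiarity_raw: int
    samples: Samples | None = None
    events: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.presentation_ms <= 0 or self.presentation_ms > 5000:
            raise ValueError("presentation_ms must lie in (0, 5000]")
        for name in ("confidence_raw", "familiarity_raw"):
            v = getattr(self, name)
            if v not in range(1, 7):
                raise ValueError(f"{name} must be an integer in 1..6, got {v!r}")


# ---------------------------------------------------------------------------
# Samples I/O
# ---------------------------------------------------------------------------


def _samples_from_frame(df: pd.DataFrame) -> dict[str, Samples]:
    out: dict[str, Samples] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        t = g["t_ms"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"trial {trial_id!r}: timestamps not strictly increasing")
        x = pd.to_numeric(g["x_px"], errors="coerce").to_numpy(dtype=float)
        y = pd.to_numeric(g["y_px"], errors="coerce").to_numpy(dtype=float)
        valid = g["valid"].astype(bool).to_numpy() & ~np.isnan(x) & ~np.isnan(y)
        out[str(trial_id)] = Samples(t, x, y, valid)
    return out


def _read_samples_csv(path: Path) -> dict[str, Samples]:
    df = pd.read_csv(path, dtype={"trial_id": str}, float_precision="round_trip")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"samples CSV missing columns: {sorted(missing)}")
    return _samples_from_frame(df)


def _read_samples_asc(path: Path) -> dict[str, Samples]:
    """Minimal ASC-like adapter.

    Recognised lines: ``START <trial_id>``, sample lines ``<t> <x> <y>``
    (a ``.`` in place of a coordinate marks track loss), everything else
    ignored. This mirrors EyeLink text exports closely enough for plumbing.
    """
    trials: dict[str, list[GazeSample]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "START":
                current = parts[1] if len(parts) > 1 else str(len(trials))
                trials.setdefault(current, [])
            elif current is not None and _is_number(parts[0]) and len(parts) >= 3:
                t = float(parts[0])
                try:
                    x, y = float(parts[1]), float(parts[2])
                    valid = not (np.isnan(x) or np.isnan(y))
                except ValueError:
                    x, y, valid = np.nan, np.nan, False
                trials[current].append(GazeSample(t, x, y, valid))
    return {tid: Samples.from_records(recs) for tid, recs in trials.items()}


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_samples(path: str | Path, dialect: str = "csv") -> dict[str, Samples]:
    """Read gaze samples grouped by trial.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"csv"`` — canonical ``trial_id,t_ms,x_px,y_px,valid`` table, or
        ``"asc"`` — EyeLink-ASC-like line format.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_samples_csv(path)
    if dialect == "asc":
        return _read_samples_asc(path)
    raise ValueError(f"unknown samples dialect {dialect!r}")


def write_samples(trials: dict[str, Samples], path: str | Path) -> None:
    """Write trials to the canonical CSV dialect (round-trips bit-exactly)."""
    frames = []
    for trial_id, s in trials.items():
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "t_ms": s.t_ms,
                    "x_px": s.x_px,
                    "y_px": s.y_px,
                    "valid": s.valid.astype(int),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SAMPLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")  # %.17g round-trips doubles


# ---------------------------------------------------------------------------
# Trial metadata I/O
# ---------------------------------------------------------------------------


def read_trials(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype={"trial_id": str, "subject_id": str, "image_id": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrialRecord(
                trial_id=str(row.trial_id),
                subject_id=str(row.subject_id),
                group=str(row.group),
                image_id=str(row.image_id),
                task=str(row.task),
                presentation_ms=float(row.presentation_ms),
                answer=str(row.answer),
                correct=bool(row.correct),
                confidence_raw=int(row.confidence_raw),
                familiarity_raw=int(row.familiarity_raw),
            )
        )
    return records


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "subject_id": t.subject_id,
                "group": t.group,
                "image_id": t.image_id,
                "task": t.task,
                "presentation_ms": t.presentation_ms,
                "answer": t.answer,
                "correct": int(t.correct),
                "confidence_raw": t.confidence_raw,
                "familiarity_raw": t.familiarity_raw,
            }
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def downsample_2k_to_1k(samples: Samples) -> Samples:
    """Decimate nominal 2 kHz samples to 1 kHz.

    Consecutive pairs are averaged position-wise; the earlier timestamp of
    each pair is kept and validity is the AND of the pair. An odd trailing
    sample is kept as-is with a warning.
    """
    n = len(samples)
    if n == 0:
        return samples
    n_pairs = n // 2
    odd = n % 2 == 1
    t = samples.t_ms[: 2 * n_pairs : 2]
    x = (samples.x_px[: 2 * n_pairs : 2] + samples.x_px[1 : 2 * n_pairs : 2]) / 2.0
    y = (samples.y_px[: 2 * n_pairs : 2] + samples.y_px[1 : 2 * n_pairs : 2]) / 2.0
    valid = samples.valid[: 2 * n_pairs : 2] & samples.valid[1 : 2 * n_pairs : 2]
    if odd:
        warnings.warn("odd trailing sample kept as-is during 2k->1k downsampling", stacklevel=2)
        t = np.append(t, samples.t_ms[-1])
        x = np.append(x, samples.x_px[-1])
        y = np.append(y, samples.y_px[-1])
        valid = np.append(valid, samples.valid[-1])
    return Samples(t, x, y, valid)
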