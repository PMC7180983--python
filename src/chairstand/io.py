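"""Data model and CSV I/O for chair-stand distance signals and manual counts.

The chair-stand sensor reports the distance (cm) between a subject's back and
the chair backrest at a fixed 10 Hz cadence.  Signals are exchanged as
two-column CSV files ``time_s,distance_cm`` with a mandatory header; the time
column is advisory only -- sample order is authoritative and sample *i* is
taken to occur at exactly ``i / rate_hz`` seconds.  Missing values (produced
by preprocessing, never by the device) are serialized as the literal token
``NA``.

Manual-count annotations (one row per subject: how many sit-to-stand
transitions a trained rater counted, and how many of those reached a complete
upright posture) travel as ``subject_id,valid_count,total_count`` CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DistanceSignal",
    "AnnotationRecord",
    "SignalFormatError",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
]

MISSING_TOKEN = "NA"


class SignalFormatError(ValueError):
    """Raised for malformed signal or annotation files."""


@dataclass(frozen=True)
class DistanceSignal:
    """A uniformly sampled back-to-backrest distance trace.

    Parameters
    ----------
    samples:
        Distance values in cm.  Raw device recordings are finite and
        non-negative; after preprocessing, entries may be NaN (the missing
        marker).
    rate_hz:
        Sampling rate in Hz.  The device emits one reading every 100 ms,
        i.e. 10 Hz.
    subject_id:
        Opaque label used to join signals with annotations.
    """

    samples: np.ndarray
    rate_hz: float = 10.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based: first sample at t = 0)."""
        return np.arange(self.samples.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def with_samples(self, samples: np.ndarray) -> "DistanceSignal":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class AnnotationRecord:
    """Manual count for one subject: valid and total sit-to-stand events."""

    subject_id: str
    valid_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.valid_count <= self.total_count):
            raise ValueError(
                f"need 0 <= valid_count <= total_count, got "
                f"valid={self.valid_count}, total={self.total_count}"
            )


def read_signal(path: str | Path, rate_hz: float = 10.0) -> DistanceSignal:
    """Read a ``time_s,distance_cm`` CSV into a :class:`DistanceSignal`.

    The header row is mandatory.  Distances must be finite and non-negative;
    the token ``NA`` is accepted as the missing marker (files written back
    after preprocessing).  Malformed rows are reported with their 1-based
    file row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    if rate_hz <= 0:
        raise ValueError(f"rate_hz must be positive, got {rate_hz}")
    lines = path.read_text().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise SignalFormatError(f"{path}: empty signal file")
    values: list[float] = []
    for rownum, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SignalFormatError(
                f"{path}: malformed row {rownum}: expected 2 columns, got {len(parts)}"
            )
        token = parts[1].strip()
        if token == MISSING_TOKEN:
            values.append(math.nan)
            continue
        try:
            value = float(token)
        except ValueError:
            raise SignalFormatError(
                f"{path}: malformed row {rownum}: non-numeric distance {token!r}"
            ) from None
        if math.isnan(value) or math.isinf(value) or value < 0:
            raise SignalFormatError(
                f"{path}: malformed row {rownum}: distance must be finite and "
                f"non-negative, got {token}"
            )
        values.append(value)
    if not values:
        raise SignalFormatError(f"{path}: no data rows")
    return DistanceSignal(np.array(values), rate_hz=rate_hz, subject_id=path.stem)


def write_signal(signal: DistanceSignal, path: str | Path) -> None:
    """Write a signal as ``time_s,distance_cm`` CSV (missing values as ``NA``).

    Round-trips through :func:`read_signal` to within 1e-6 cm per sample.
    """
    if len(signal) == 0:
        raise ValueError("refusing to write an empty signal")
    path = Path(path)
    rows = ["time_s,distance_cm"]
    for t, x in zip(signal.times, signal.samples):
        token = MISSING_TOKEN if math.isnan(x) else format(x, ".6f")
        rows.append(f"{t:.3f},{token}")
    path.write_text("\n".join(rows) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a ``subject_id,valid_count,total_count`` CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise SignalFormatError(f"{path}: empty annotation file")
    records = []
    for rownum, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise SignalFormatError(
                f"{path}: malformed row {rownum}: expected 3 columns"
            )
        try:
            valid, total = int(parts[1]), int(parts[2])
        except ValueError:
            raise SignalFormatError(
                f"{path}: malformed row {rownum}: counts must be integers"
            ) from None
        try:
            records.append(AnnotationRecord(parts[0], valid, total))
        except ValueError as exc:
            raise SignalFormatError(f"{path}: malformed row {rownum}: {exc}") from None
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = ["subject_id,valid_count,total_count"]
    rows += [f"{r.subject_id},{r.valid_count},{r.total_count}" for r in records]
    Path(path).write_text("\n".join(rows) + "\n")
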