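"""The two sit-to-stand detection algorithms for 30-s chair-stand signals.

Both algorithms take the raw back-to-backrest distance trace and return the
ordered list of detected sit-to-stand transitions.

Algorithm v1 (moving median + peak thresholds)
    Readings above 70 cm are sensor outliers and are reset to 15 cm (a
    typical sitting distance).  A 0.7-s moving median removes narrow spikes.
    Local maxima of the filtered signal separated by less than the peak
    distance threshold (PDT) are merged into single peaks; PDT is adaptive,
    the median inter-maximum distance multiplied by the distance factor (DF).
    Peaks exceeding the peak height threshold (PHT) are counted.

Algorithm v2 (moving minimum + adaptive sitting-standing threshold)
    Readings above 99 cm are nulled to NaN rather than reset.  A 0.7-s moving
    minimum tracks the envelope of local minima, which upward spikes cannot
    reach.  The filtered signal is compared against the sitting-standing
    threshold (SST), an adaptive curve lying between the 4-s moving minimum
    and the 4-s moving median of the preprocessed signal, weighted by the
    adaptive threshold weight (ATW).  Rising edges of the resulting binary
    standing signal are candidate stand-ups; candidates closer than the
    minimum peak distance (MPD, seconds) are merged, then peaks closer than
    the minimum samples between peaks (MSBP, samples) are merged, and peaks
    not exceeding the minimum subject distance (MSD, cm) are discarded.

All threshold comparisons are strict (a value "over 70 cm" means > 70).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .filters import moving_median, moving_minimum, window_samples
from .io import DistanceSignal

__all__ = [
    "ParamsV1",
    "ParamsV2",
    "DetectionEvent",
    "DetectionResult",
    "UnusableSignalError",
    "preprocess_v1",
    "preprocess_v2",
    "compute_sst",
    "rising_edges",
    "local_maxima",
    "detect_v1",
    "detect_v2",
]


class UnusableSignalError(ValueError):
    """Raised when a recording cannot be processed (e.g. all samples nulled)."""


@dataclass(frozen=True)
class ParamsV1:
    """Algorithm-v1 parameters.

    ``distance_factor`` (DF) and ``peak_height_threshold_cm`` (PHT) are the
    two tunable thresholds; defaults were set by grid calibration on
    synthetic annotated signals and are exposed through config and CLI.
    """

    outlier_ceiling_cm: float = 70.0
    outlier_reset_cm: float = 15.0
    median_window_s: float = 0.7
    distance_factor: float = 0.5
    peak_height_threshold_cm: float = 30.0

    def __post_init__(self) -> None:
        if not self.outlier_ceiling_cm > self.outlier_reset_cm > 0:
            raise ValueError("need outlier_ceiling_cm > outlier_reset_cm > 0")
        if self.distance_factor <= 0:
            raise ValueError("distance_factor must be positive")
        if self.peak_height_threshold_cm <= 0:
            raise ValueError("peak_height_threshold_cm must be positive")


@dataclass(frozen=True)
class ParamsV2:
    """Algorithm-v2 parameters (ATW, MPD, MSBP, MSD and window lengths)."""

    outlier_ceiling_cm: float = 99.0
    minimum_window_s: float = 0.7
    sst_window_s: float = 4.0
    atw: float = 0.5
    mpd_s: float = 1.0
    msbp: int = 5
    msd_cm: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.atw <= 1.0:
            raise ValueError(f"atw must lie in [0, 1], got {self.atw}")
        if self.mpd_s <= 0:
            raise ValueError("mpd_s must be positive")
        if self.msbp < 0 or int(self.msbp) != self.msbp:
            raise ValueError("msbp must be a non-negative integer")
        if self.msd_cm <= 0:
            raise ValueError("msd_cm must be positive")


@dataclass(frozen=True)
class DetectionEvent:
    """One detected sit-to-stand transition."""

    sample_index: int
    time_s: float
    height_cm: float


@dataclass(frozen=True)
class DetectionResult:
    """Ordered detected transitions plus the final count."""

    events: tuple[DetectionEvent, ...]
    count: int = field(init=False)

    def __post_init__(self) -> None:
        idx = [e.sample_index for e in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("events must be strictly increasing in sample_index")
        object.__setattr__(self, "count", len(self.events))

    @property
    def times_s(self) -> np.ndarray:
        return np.array([e.time_s for e in self.events])


def _make_result(indices, heights, rate_hz: float) -> DetectionResult:
    events = tuple(
        DetectionEvent(int(i), float(i / rate_hz), float(h))
        for i, h in zip(indices, heights)
    )
    return DetectionResult(events)


# ---------------------------------------------------------------------------
# Algorithm v1


def preprocess_v1(signal: DistanceSignal, params: ParamsV1 | None = None) -> DistanceSignal:
    """Reset out-of-range readings (> ceiling) to the sitting estimate."""
    params = params or ParamsV1()
    if len(signal) == 0:
        raise ValueError("empty signal")
    x = signal.samples.copy()
    x[x > params.outlier_ceiling_cm] = params.outlier_reset_cm
    return signal.with_samples(x)


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau reports its first index."""
    peaks, props = find_peaks(np.asarray(values, dtype=float), plateau_size=1)
    return props["left_edges"]


def detect_v1(signal: DistanceSignal, params: ParamsV1 | None = None) -> DetectionResult:
    """Run Algorithm v1 and return the detected transitions."""
    params = params or ParamsV1()
    pre = preprocess_v1(signal, params)
    w = window_samples(params.median_window_s, signal.rate_hz)
    if len(pre) < w:
        raise UnusableSignalError(
            f"signal of {len(pre)} samples is shorter than the {w}-sample filter window"
        )
    filtered = moving_median(pre.samples, params.median_window_s, signal.rate_hz)
    maxima = local_maxima(filtered)
    if maxima.size == 0:
        return DetectionResult(())
    # PDT: median inter-maximum distance (samples, over all strict local
    # maxima before any merging) scaled by DF.  Fewer than two maxima leave
    # the PDT undefined; no merging is applied then.
    if maxima.size >= 2:
        pdt = float(np.median(np.diff(maxima))) * params.distance_factor
    else:
        pdt = 0.0
    groups: list[list[int]] = [[int(maxima[0])]]
    for m in maxima[1:]:
        if m - groups[-1][-1] < pdt:
            groups[-1].append(int(m))
        else:
            groups.append([int(m)])
    indices, heights = [], []
    for grp in groups:
        vals = filtered[grp]
        j = grp[int(np.argmax(vals))]  # argmax -> earliest index on ties
        h = float(filtered[j])
        if h > params.peak_height_threshold_cm:
            indices.append(j)
            heights.append(h)
    return _make_result(indices, heights, signal.rate_hz)


# ---------------------------------------------------------------------------
# Algorithm v2


def preprocess_v2(signal: DistanceSignal, params: ParamsV2 | None = None) -> DistanceSignal:
    """Null out-of-range readings (> ceiling) to NaN."""
    params = params or ParamsV2()
    if len(signal) == 0:
        raise ValueError("empty signal")
    x = signal.samples.copy()
    x[x > params.outlier_ceiling_cm] = np.nan
    if np.all(np.isnan(x)):
        raise UnusableSignalError("all samples exceed the outlier ceiling")
    return signal.with_samples(x)


def compute_sst(
    preprocessed, params: ParamsV2 | None = None, rate_hz: float = 10.0
) -> np.ndarray:
    """Sitting-standing threshold: adaptive curve between the long-window
    moving minimum and moving median of the preprocessed signal.

    ``SST[i] = movmin[i] + ATW * (movmed[i] - movmin[i])`` with both filters
    using ``sst_window_s`` (4 s by default), so ATW=0 reproduces the moving
    minimum and ATW=1 the moving median.
    """
    params = params or ParamsV2()
    x = np.asarray(preprocessed, dtype=float)
    mmin = moving_minimum(x, params.sst_window_s, rate_hz)
    mmed = moving_median(x, params.sst_window_s, rate_hz)
    return mmin + params.atw * (mmed - mmin)


def rising_edges(binary) -> np.ndarray:
    """Indices i > 0 where the binary standing signal steps 0 -> 1.

    An initial standing state (binary[0] == 1) is not an edge: the test
    scores stand-ups, and a subject already up at t=0 has not performed one.
    """
    b = np.asarray(binary, dtype=float)
    b = np.where(np.isnan(b), 0.0, b)
    return np.flatnonzero((b[1:] == 1) & (b[:-1] == 0)) + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) half-open."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _group_by_gap(indices: Sequence[int], gap: float) -> list[list[int]]:
    groups: list[list[int]] = [[indices[0]]]
    for i in indices[1:]:
        if i - groups[-1][-1] < gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def detect_v2(signal: DistanceSignal, params: ParamsV2 | None = None) -> DetectionResult:
    """Run Algorithm v2 and return the detected transitions."""
    params = params or ParamsV2()
    pre = preprocess_v2(signal, params)
    w = window_samples(params.sst_window_s, signal.rate_hz)
    if len(pre) < w:
        raise UnusableSignalError(
            f"signal of {len(pre)} samples is shorter than the {w}-sample SST window"
        )
    filtered = moving_minimum(pre.samples, params.minimum_window_s, signal.rate_hz)
    sst = compute_sst(pre.samples, params, signal.rate_hz)
    with np.errstate(invalid="ignore"):
        binary = np.greater(filtered, sst)  # NaN on either side -> sitting
    binary &= ~(np.isnan(filtered) | np.isnan(sst))
    edges = rising_edges(binary.astype(int))
    if edges.size == 0:
        return DetectionResult(())
    runs = _runs(binary)
    run_starts = np.array([r[0] for r in runs])

    def run_of(edge: int) -> tuple[int, int]:
        k = int(np.searchsorted(run_starts, edge, side="right")) - 1
        return runs[k]

    # Stage 1: merge standing events closer than MPD (seconds).
    mpd_samples = params.mpd_s * signal.rate_hz
    peaks: list[set[tuple[int, int]]] = [
        {run_of(e) for e in grp} for grp in _group_by_gap(list(edges), mpd_samples)
    ]

    # Reported peak height/index are read off the preprocessed signal
    # (NaN-aware): the highest actual reading within the above-threshold
    # extent.  The MSD discard instead judges the peak on the moving-minimum
    # envelope, where spurious spikes cannot inflate a small peak above the
    # threshold -- the same mechanism that makes the binary signal robust.
    def summarize(extent: set[tuple[int, int]]) -> tuple[int, float, float]:
        idx = np.concatenate([np.arange(a, b) for a, b in sorted(extent)])
        vals = pre.samples[idx]
        if np.isnan(vals).all():  # every reading in the extent was nulled
            vals = filtered[idx]
        j = int(idx[int(np.nanargmax(vals))])
        v = pre.samples[j]
        envelope = float(np.nanmax(filtered[idx]))
        return j, float(v if not np.isnan(v) else filtered[j]), envelope

    # Stage 2: merge peaks closer than MSBP (samples).  Peak distance is the
    # gap between their above-threshold extents: the number of consecutive
    # sitting-state samples separating them.
    merged: list[set[tuple[int, int]]] = [peaks[0]]
    for p in peaks[1:]:
        prev_end = max(b for _, b in merged[-1])
        next_start = min(a for a, _ in p)
        if next_start - prev_end < params.msbp:
            merged[-1] |= p
        else:
            merged.append(p)
    # Stage 3: discard peaks whose envelope height does not exceed MSD (cm).
    indices, heights = [], []
    for extent in merged:
        j, h, envelope = summarize(extent)
        if envelope > params.msd_cm:
            indices.append(j)
            heights.append(h)
    order = np.argsort(indices)
    return _make_result(
        [indices[k] for k in order], [heights[k] for k in order], signal.rate_hz
    )
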