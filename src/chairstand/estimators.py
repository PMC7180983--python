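"""Scikit-learn-style estimator interface to the two detectors.

``ChairStandDetectorV1`` and ``ChairStandDetectorV2`` expose the detection
algorithms as estimators: constructor arguments are the algorithm
thresholds, ``predict`` maps a sequence of :class:`DistanceSignal` objects
to per-signal transition counts, and ``fit`` performs the grid calibration
against manually annotated counts (minimizing mean absolute count error),
after which the tuned thresholds are available both as updated params and in
``best_params_``.  Both classes compose with ``sklearn.base.clone`` and
``get_params``/``set_params``.

X is a list/sequence of signals rather than a 2-D array: recordings differ
in length and carry their own sampling rate.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .calibrate import CalibrationSet, calibrate
from .detect import (
    DetectionResult,
    ParamsV1,
    ParamsV2,
    detect_v1,
    detect_v2,
)
from .io import AnnotationRecord, DistanceSignal

__all__ = ["ChairStandDetectorV1", "ChairStandDetectorV2"]


class _BaseChairStandDetector(BaseEstimator):
    _algorithm: str
    _params_cls: type
    _detect = None

    def _make_params(self):
        return self._params_cls(**self.get_params())

    def detect(self, signal: DistanceSignal) -> DetectionResult:
        """Full detection result (event indices, times, heights) for one signal."""
        return type(self)._detect(signal, self._make_params())

    def predict(self, X: Sequence[DistanceSignal]) -> np.ndarray:
        """Transition count for each signal in X."""
        return np.array([self.detect(s).count for s in X], dtype=int)

    def fit(
        self,
        X: Sequence[DistanceSignal],
        y: Sequence[int] | Sequence[AnnotationRecord],
        param_grid: Mapping[str, Sequence] | None = None,
    ):
        """Calibrate thresholds on annotated signals by exhaustive grid search.

        y may be plain integer counts or :class:`AnnotationRecord` objects
        (their valid counts are used).  ``param_grid`` maps parameter names
        to candidate values; omitted parameters keep their current setting.
        """
        records = [
            r
            if isinstance(r, AnnotationRecord)
            else AnnotationRecord(getattr(x, "subject_id", str(i)), int(r), int(r))
            for i, (x, r) in enumerate(zip(X, y))
        ]
        if param_grid is None:
            param_grid = self._default_grid()
        current = self.get_params()
        full_grid = {
            name: list(param_grid.get(name, [current[name]])) for name in current
        }
        cal_set = CalibrationSet(tuple(zip(X, records)), target="valid")
        outcome = calibrate(cal_set, self._algorithm, full_grid)
        self.set_params(**outcome.best_params)
        self.best_params_ = outcome.best_params
        self.mean_abs_error_ = outcome.mean_abs_error
        self.mean_bias_ = outcome.mean_bias
        self.error_table_ = outcome.table
        return self

    def score(self, X, y) -> float:
        """Negative mean absolute count error (greater is better)."""
        counts = self.predict(X)
        targets = np.array(
            [r.valid_count if isinstance(r, AnnotationRecord) else int(r) for r in y]
        )
        return -float(np.mean(np.abs(counts - targets)))


class ChairStandDetectorV1(_BaseChairStandDetector):
    """Moving-median detector (Algorithm v1).

    Suited to smooth recordings with sparse narrow artefacts; known to
    degrade when spikes arrive in clusters dense enough to pass a 0.7-s
    median window.
    """

    _algorithm = "v1"
    _params_cls = ParamsV1
    _detect = staticmethod(detect_v1)

    def __init__(
        self,
        outlier_ceiling_cm: float = 70.0,
        outlier_reset_cm: float = 15.0,
        median_window_s: float = 0.7,
        distance_factor: float = 0.5,
        peak_height_threshold_cm: float = 30.0,
    ):
        self.outlier_ceiling_cm = outlier_ceiling_cm
        self.outlier_reset_cm = outlier_reset_cm
        self.median_window_s = median_window_s
        self.distance_factor = distance_factor
        self.peak_height_threshold_cm = peak_height_threshold_cm

    @staticmethod
    def _default_grid():
        return {
            "distance_factor": [0.25, 0.5, 0.75, 1.0],
            "peak_height_threshold_cm": [20.0, 25.0, 30.0, 35.0, 40.0],
        }


class ChairStandDetectorV2(_BaseChairStandDetector):
    """Moving-minimum detector with adaptive threshold (Algorithm v2).

    Robust to spike clusters: nulled outliers and upward spikes cannot reach
    the envelope of local minima that the 0.7-s moving minimum tracks.
    """

    _algorithm = "v2"
    _params_cls = ParamsV2
    _detect = staticmethod(detect_v2)

    def __init__(
        self,
        outlier_ceiling_cm: float = 99.0,
        minimum_window_s: float = 0.7,
        sst_window_s: float = 4.0,
        atw: float = 0.5,
        mpd_s: float = 1.0,
        msbp: int = 5,
        msd_cm: float = 25.0,
    ):
        self.outlier_ceiling_cm = outlier_ceiling_cm
        self.minimum_window_s = minimum_window_s
        self.sst_window_s = sst_window_s
        self.atw = atw
        self.mpd_s = mpd_s
        self.msbp = msbp
        self.msd_cm = msd_cm

    @staticmethod
    def _default_grid():
        return {
            "atw": [0.25, 0.5, 0.75],
            "mpd_s": [0.5, 1.0, 1.5],
            "msbp": [3, 5, 8],
            "msd_cm": [20.0, 25.0, 30.0],
        }
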