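"""NaN-aware centered sliding-window filters shared by both detectors.

Both chair-stand algorithms rest on short moving filters: a 0.7-s moving
median (robust to narrow spikes) and a 0.7-s moving minimum (which tracks the
envelope of local minima and ignores upward noise entirely).  Windows are
centered and shrink at the signal edges; missing values (NaN) inside a window
are simply excluded, and a window containing no finite value yields NaN.

Window lengths are specified in seconds and converted to samples as
``round(window_s * rate_hz)``, promoted to the next odd count so the window
has a symmetric center (0.7 s at 10 Hz -> 7 samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["moving_median", "moving_minimum", "window_samples"]


def window_samples(window_s: float, rate_hz: float) -> int:
    """Window length in samples: round to nearest, promote even to odd."""
    if window_s <= 0 or rate_hz <= 0:
        raise ValueError("window_s and rate_hz must be positive")
    w = int(round(window_s * rate_hz))
    if w < 1:
        raise ValueError(
            f"window of {window_s} s at {rate_hz} Hz spans less than one sample"
        )
    if w % 2 == 0:
        w += 1
    return w


def _rolling(samples, window_s: float, rate_hz: float) -> pd.core.window.Rolling:
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    w = window_samples(window_s, rate_hz)
    # min_periods=1: edges shrink to the available samples; NaNs are skipped.
    return pd.Series(x).rolling(w, center=True, min_periods=1)


def moving_median(samples, window_s: float, rate_hz: float) -> np.ndarray:
    """Centered moving median over the non-missing values of each window.

    An even count of finite values in a window yields the mean of the two
    central order statistics.
    """
    return _rolling(samples, window_s, rate_hz).median().to_numpy()


def moving_minimum(samples, window_s: float, rate_hz: float) -> np.ndarray:
    """Centered moving minimum over the non-missing values of each window."""
    return _rolling(samples, window_s, rate_hz).min().to_numpy()
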