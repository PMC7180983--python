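"""Inter-rater reliability and classifier-performance statistics.

The device is validated as if it were a second human rater: per-subject
scores from the manual count and from an algorithm form an n x 2 rating
table, and agreement is quantified by the single-rater, absolute-agreement,
two-way intraclass correlation coefficient, ICC(A,1) in McGraw & Wong's
nomenclature:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the subject, rater and residual mean squares of the two-way
ANOVA.  The 95% CI uses the F-distribution bounds with Satterthwaite
degrees of freedom; the significance test is F = MSR/MSE against
F(n-1, (n-1)(k-1)).  Point estimates are interpreted on the conventional
reliability scale: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >= 0.9
excellent; a "supported" band classifies the CI lower bound, i.e. the level
of reliability the data can actually guarantee.

Normative classification is evaluated against the no-information rate (NIR,
the frequency of the most common class): accuracy with an exact
Clopper-Pearson 95% CI, a one-sided exact binomial test of accuracy > NIR,
Cohen's effect size h = 2 asin(sqrt(acc)) - 2 asin(sqrt(NIR)), and the power
of the one-sample proportion test via the arcsine-transform normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RatingTable",
    "ICCResult",
    "ClassifierReport",
    "icc_a1",
    "icc_band",
    "classifier_report",
    "cohen_h",
    "proportion_test_power",
]

_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


def icc_band(value: float) -> str:
    """Reliability band for an ICC value: left-closed at 0.5 / 0.75 / 0.9."""
    for upper, label in _BANDS:
        if value < upper:
            return label
    return "excellent"


@dataclass(frozen=True)
class RatingTable:
    """n subjects x 2 raters (manual count, algorithm count)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", arr)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"expected an n x 2 table, got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if np.isnan(arr).any():
            raise ValueError("rating table must have no missing cells")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    p_value: float
    band: str
    supported_band: str


def icc_a1(table: RatingTable | np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): single-rater, absolute-agreement, two-way model."""
    if not isinstance(table, RatingTable):
        table = RatingTable(np.asarray(table))
    X = table.scores
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((X - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("undefined ICC: zero total variance in the rating table")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse > 0:
        f_stat = msr / mse
        p_value = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
            fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
            ci_low = n * (msr - fl * mse) / (
                fl * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            ci_high = n * (fu * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * fu * msr
            )
        else:
            ci_low = ci_high = icc
    else:
        # Perfect reproduction of every score: no residual variance.
        f_stat, p_value = np.inf, 0.0
        ci_low = ci_high = icc
    ci_low = float(min(ci_low, icc))
    ci_high = float(max(ci_high, icc))
    return ICCResult(
        icc=float(icc),
        ci_low=ci_low,
        ci_high=ci_high,
        f_stat=float(f_stat),
        p_value=p_value,
        band=icc_band(icc),
        supported_band=icc_band(ci_low),
    )


def cohen_h(p1: float, p2: float) -> float:
    """Cohen's effect size h for two proportions (arcsine transform)."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion outside [0, 1]: {p}")
    return float(2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2)))


def proportion_test_power(h: float, n: int, alpha: float = 0.05) -> float:
    """Power of the one-sided one-sample proportion test (normal approx.).

    Matches the arcsine-transform convention: power = Phi(h*sqrt(n) - z_(1-a)).
    At h = 0 the power equals alpha by construction.
    """
    z = sps.norm.ppf(1 - alpha)
    return float(sps.norm.cdf(h * np.sqrt(n) - z))


@dataclass(frozen=True)
class ClassifierReport:
    accuracy: float
    ci_low: float
    ci_high: float
    nir: float
    p_vs_nir: float
    effect_size_h: float
    power: float
    n: int


def _clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _binom_tail_ge(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    return float(sps.binom.sf(k - 1, n, p))


def classifier_report(
    true_classes: Sequence, predicted_classes: Sequence, nir: float, alpha: float = 0.05
) -> ClassifierReport:
    """Accuracy vs the no-information rate with exact CI, test, h and power."""
    if len(true_classes) != len(predicted_classes):
        raise ValueError("true and predicted class sequences differ in length")
    n = len(true_classes)
    if n == 0:
        raise ValueError("empty class sequences")
    if not 0.0 < nir < 1.0:
        raise ValueError(f"nir must lie strictly in (0, 1), got {nir}")
    matches = int(sum(t == p for t, p in zip(true_classes, predicted_classes)))
    accuracy = matches / n
    ci_low, ci_high = _clopper_pearson(matches, n)
    p_vs_nir = _binom_tail_ge(matches, n, nir)
    h = cohen_h(accuracy, nir)
    power = proportion_test_power(h, n, alpha)
    return ClassifierReport(
        accuracy=accuracy,
        ci_low=ci_low,
        ci_high=ci_high,
        nir=nir,
        p_vs_nir=p_vs_nir,
        effect_size_h=h,
        power=power,
        n=n,
    )
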