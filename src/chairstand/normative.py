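"""Normative classification of 30-s chair-stand scores.

Published normative standards band the expected score by gender and age:
a score below the band's 25th percentile is *below average*, a score above
the 75th percentile is *above average*, and anything in between (inclusive
at both percentiles) is *average*.  An 82-year-old woman scoring 11 is
average, while a 63-year-old woman with the same score is below average --
the expected decline with normal aging is built into the bands.

The table shipped here (:func:`default_table`) is a synthetic illustrative
fixture consistent with those worked examples, NOT a reproduction of any
published normative table; replace it with your reference values via
:meth:`NormativeTable.from_csv` (columns ``gender,age_low,age_high,p25,p75``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "NormativeTable",
    "ClassOutcome",
    "NormLookupError",
    "classify_score",
    "default_table",
]

ClassLabel = Literal["below_average", "average", "above_average"]


class NormLookupError(KeyError):
    """No normative band covers the given gender/age."""


@dataclass(frozen=True)
class NormativeTable:
    """Gender x age-band -> (25th percentile, 75th percentile) score ranges."""

    entries: pd.DataFrame  # columns: gender, age_low, age_high, p25, p75

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries, columns=["gender", "age_low", "age_high", "p25", "p75"])
        object.__setattr__(self, "entries", df)
        if (df["p25"] > df["p75"]).any():
            raise ValueError("p25 must not exceed p75 in any band")
        for gender, grp in df.groupby("gender"):
            bands = grp.sort_values("age_low")
            prev_high = None
            for _, row in bands.iterrows():
                if row["age_low"] > row["age_high"]:
                    raise ValueError("age_low must not exceed age_high")
                if prev_high is not None and row["age_low"] <= prev_high:
                    raise ValueError(f"overlapping age bands for gender {gender!r}")
                prev_high = row["age_high"]

    def band(self, gender: str, age: float) -> tuple[float, float]:
        df = self.entries
        hit = df[
            (df["gender"] == gender) & (df["age_low"] <= age) & (age <= df["age_high"])
        ]
        if hit.empty:
            raise NormLookupError(
                f"no norm available for gender={gender!r}, age={age}"
            )
        row = hit.iloc[0]
        return float(row["p25"]), float(row["p75"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormativeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass(frozen=True)
class ClassOutcome:
    subject_id: str
    score: int
    label: ClassLabel


def classify_score(
    score: float, gender: str, age: float, table: NormativeTable
) -> ClassLabel:
    """Assign below_average / average / above_average for one score.

    Boundary scores equal to either percentile are classed *average*
    (percentile-inclusive reading of "between the 25th and 75th").
    """
    p25, p75 = table.band(gender, age)
    if score < p25:
        return "below_average"
    if score > p75:
        return "above_average"
    return "average"


def default_table() -> NormativeTable:
    """Synthetic illustrative normative table (user-replaceable).

    Values are chosen to be consistent with the canonical worked examples
    (female 60-64 band 12-17, female 80-84 band 10-15, male 60-64 band
    14-19) and decline smoothly with age; they are not a published table.
    """
    rows = [
        ("female", 60, 64, 12, 17),
        ("female", 65, 69, 11, 16),
        ("female", 70, 74, 10, 15),
        ("female", 75, 79, 10, 15),
        ("female", 80, 84, 10, 15),
        ("female", 85, 89, 8, 13),
        ("female", 90, 94, 4, 11),
        ("male", 60, 64, 14, 19),
        ("male", 65, 69, 12, 18),
        ("male", 70, 74, 12, 17),
        ("male", 75, 79, 11, 17),
        ("male", 80, 84, 10, 15),
        ("male", 85, 89, 8, 14),
        ("male", 90, 94, 7, 12),
    ]
    return NormativeTable(
        pd.DataFrame(rows, columns=["gender", "age_low", "age_high", "p25", "p75"])
    )
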