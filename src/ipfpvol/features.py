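"""The 48-variable design space: 12 dimensional variables + 36 biomarker ratios.

"Dimensional" variables are the untransformed predictors — the three risk
factors (age, gender, BMI) and the nine serum concentrations.  Every
unordered pair of distinct biomarkers contributes one ratio column, C(9,2) =
36 of them, oriented by the canonical biomarker order (earlier / later).
Because the literature sometimes names a ratio in the opposite orientation
(e.g. "chemerin/adiponectin_HMW"), :meth:`FeatureMatrix.resolve` accepts
either form and returns the stored column or its reciprocal.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterator, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import BIOMARKERS

RISK_FACTORS: tuple[str, ...] = ("age", "gender", "bmi")
DIMENSIONAL: tuple[str, ...] = RISK_FACTORS + BIOMARKERS  # 12 columns

RATIO_PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(BIOMARKERS, 2))


def ratio_name(numerator: str, denominator: str) -> str:
    return f"{numerator}/{denominator}"


RATIO_NAMES: tuple[str, ...] = tuple(ratio_name(a, b) for a, b in RATIO_PAIRS)
FEATURE_NAMES: tuple[str, ...] = DIMENSIONAL + RATIO_NAMES  # the 48 features


@dataclass
class FeatureMatrix:
    """48-column design matrix with ratio-orientation metadata."""

    data: pd.DataFrame
    orientation: dict[str, tuple[str, str]]
    subject_ids: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def has(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except KeyError:
            return False

    def resolve(self, name: str) -> np.ndarray:
        """Return the named column; a reversed ratio name yields the reciprocal."""
        if name in self.data.columns:
            return self.data[name].to_numpy()
        if "/" in name:
            num, den = name.split("/", 1)
            flipped = ratio_name(den, num)
            if flipped in self.data.columns:
                return 1.0 / self.data[flipped].to_numpy()
        raise KeyError(name)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Column-stack the resolved features, in the order given."""
        return np.column_stack([self.resolve(n) for n in names])

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "subject_id", self.subject_ids.to_numpy())
        out.to_csv(path, index=False)


def build_features(cohort: pd.DataFrame) -> FeatureMatrix:
    """Assemble the 48 features from a cohort table.

    Rows with any non-positive biomarker are rejected (dropped with a
    diagnostic): ratios would be undefined and real immunoassays cannot
    report zero under the study protocol.
    """
    bio = cohort[list(BIOMARKERS)]
    bad = (bio <= 0).any(axis=1)
    if bad.any():
        import warnings

        warnings.warn(
            f"dropping {int(bad.sum())} row(s) with non-positive biomarker values",
            RuntimeWarning,
            stacklevel=2,
        )
        cohort = cohort.loc[~bad]

    cols: dict[str, np.ndarray] = {
        name: cohort[name].to_numpy(dtype=float) for name in DIMENSIONAL
    }
    orientation: dict[str, tuple[str, str]] = {}
    for num, den in RATIO_PAIRS:
        rname = ratio_name(num, den)
        cols[rname] = cohort[num].to_numpy(dtype=float) / cohort[den].to_numpy(dtype=float)
        orientation[rname] = (num, den)

    data = pd.DataFrame(cols, index=cohort.index)[list(FEATURE_NAMES)]
    return FeatureMatrix(
        data=data,
        orientation=orientation,
        subject_ids=cohort["subject_id"].reset_index(drop=True),
    )


def invert_ratios(fm: FeatureMatrix) -> FeatureMatrix:
    """Replace every ratio column by its reciprocal; dimensional columns untouched."""
    cols: dict[str, np.ndarray] = {
        name: fm.data[name].to_numpy() for name in DIMENSIONAL
    }
    orientation: dict[str, tuple[str, str]] = {}
    for stored, (num, den) in fm.orientation.items():
        flipped = ratio_name(den, num)
        cols[flipped] = 1.0 / fm.data[stored].to_numpy()
        orientation[flipped] = (den, num)
    data = pd.DataFrame(cols, index=fm.data.index)
    return FeatureMatrix(data=data, orientation=orientation, subject_ids=fm.subject_ids)


def count_combinations(n: int, m: int) -> int:
    """Exact binomial coefficient C(n, m), integer arithmetic throughout."""
    if n < 0 or m < 0:
        raise ValueError("arguments must be non-negative")
    if m > n:
        raise ValueError(f"m={m} exceeds n={n}")
    return math.comb(n, m)


def enumerate_subsets(
    names: Sequence[str], m: int, cap: int = 2_000_000
) -> Iterator[tuple[str, ...]]:
    """Yield every size-m subset exactly once, in lexicographic index order.

    Intended as an exhaustive oracle for small candidate sets; refuses when
    the subset count exceeds ``cap``.
    """
    total = count_combinations(len(names), m)
    if total > cap:
        raise ValueError(
            f"C({len(names)},{m}) = {total} exceeds the enumeration cap {cap}"
        )
    return itertools.combinations(tuple(names), m)
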