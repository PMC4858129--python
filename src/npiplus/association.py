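"""Contingency-table association statistics.

Distribution comparisons between cohorts and between biological classes
and clinicopathological variables use the Pearson chi-square (no
continuity correction, so that Cramer's V is consistent across table
sizes) and Cramer's V,

    V = sqrt(chi2 / (n * (min(r, c) - 1))),

the classical, uncorrected statistic in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "SparseTableWarning",
    "chi_square",
    "cramers_v",
    "associate",
    "compare_distributions",
]


class SparseTableWarning(UserWarning):
    """Expected counts below 5 or empty lines dropped."""


@dataclass
class ContingencyTable:
    """An r x c table of nonnegative integer counts with axis labels."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.counts)
        arr = df.to_numpy()
        if arr.ndim != 2 or df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("cell counts must be finite and nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("cell counts must be integers")
        if arr.sum() < 1:
            raise ValueError("table total must be at least 1")
        self.counts = df.astype(int)

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        df = pd.DataFrame(counts)
        if row_labels is not None:
            df.index = list(row_labels)
        if col_labels is not None:
            df.columns = list(col_labels)
        return cls(df)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class AssociationResult:
    chi2: float
    dof: int
    p: float
    v: float
    n: int


def _effective_counts(table: ContingencyTable) -> np.ndarray:
    """Counts with all-zero rows/columns dropped (warned), validated."""
    arr = table.counts.to_numpy(dtype=float)
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn(
            "dropping all-zero row(s)/column(s) from contingency table",
            SparseTableWarning,
            stacklevel=3,
        )
        arr = arr[keep_rows][:, keep_cols]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table degenerate after dropping empty rows/columns")
    return arr


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square with margin-based expected counts.

    Returns (chi2, dof, p) with dof = (r-1)(c-1).  Cells with expected
    count below 5 trigger a SparseTableWarning but no switch to an exact
    test.
    """
    arr = _effective_counts(table)
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} cell(s) with expected count < 5",
            SparseTableWarning,
            stacklevel=2,
        )
    return float(chi2), int(dof), float(p)


def cramers_v(table: ContingencyTable) -> float:
    """Classical (uncorrected) Cramer's V of a contingency table."""
    arr = _effective_counts(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SparseTableWarning)
        chi2, _, _ = chi_square(ContingencyTable(pd.DataFrame(arr)))
    n = arr.sum()
    k = min(arr.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def associate(table: ContingencyTable) -> AssociationResult:
    """chi-square and Cramer's V of one table, as a single result object."""
    chi2, dof, p = chi_square(table)
    v = cramers_v(table)
    return AssociationResult(chi2=chi2, dof=dof, p=p, v=v, n=table.n)


def compare_distributions(
    dist_a: Mapping[str, int],
    dist_b: Mapping[str, int],
    *,
    names: tuple[str, str] = ("a", "b"),
) -> AssociationResult:
    """Compare two labelled count vectors via their 2 x k table.

    The two distributions must be over the same label set; the chi-square
    and Cramer's V of the stacked table quantify how different they are.
    Categories empty in both distributions are dropped with a warning.
    """
    missing_in_b = sorted(set(dist_a) - set(dist_b))
    missing_in_a = sorted(set(dist_b) - set(dist_a))
    if missing_in_a or missing_in_b:
        raise ValueError(
            "label sets differ: "
            f"only in first={missing_in_b}, only in second={missing_in_a}"
        )
    labels = list(dist_a)
    table = ContingencyTable.from_counts(
        [[int(dist_a[k]) for k in labels], [int(dist_b[k]) for k in labels]],
        row_labels=list(names),
        col_labels=labels,
    )
    return associate(table)
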