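"""Exact and rank-based tests for cohort comparison tables.

``fisher_exact`` is a full Freeman-Halton test: for an r x c table it
enumerates every table with the observed margins and sums the multivariate
hypergeometric probabilities of those no more probable than the observed one
(two-sided, with a small relative tolerance for floating-point ties). The
2 x 2 case is simply c = 2. ``wilcoxon_rank_sum`` is the two-sample rank-sum
test, exact for small tie-free samples and tie-corrected normal otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

ENUMERATION_GUARD = 200
_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    @classmethod
    def from_array(cls, array, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(array)
        if arr.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (arr < 0).any():
            raise ValueError("contingency table has negative cells")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("contingency table must hold integer counts")
            arr = np.round(arr).astype(int)
        return cls(
            tuple(tuple(int(x) for x in row) for row in arr),
            tuple(row_labels) if row_labels is not None else None,
            tuple(col_labels) if col_labels is not None else None,
        )

    def to_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)


def _drop_empty(arr: np.ndarray) -> np.ndarray:
    arr = arr[arr.sum(axis=1) > 0]
    return arr[:, arr.sum(axis=0) > 0]


def _log_table_prob(arr: np.ndarray, log_margins: float) -> float:
    return log_margins - gammaln(arr + 1).sum()


def fisher_exact(table: ContingencyTable | np.ndarray | list) -> float:
    """Two-sided Freeman-Halton exact p-value for an r x c table.

    All-zero rows and columns are dropped first. Enumeration is exact and
    guarded at a total of 200 observations.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    arr = _drop_empty(table.to_array())
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        # Degenerate margins admit exactly one table: the observed one.
        return 1.0
    total = int(arr.sum())
    if total > ENUMERATION_GUARD:
        raise ValueError(
            f"table total {total} exceeds the exact-enumeration guard "
            f"({ENUMERATION_GUARD}); a Monte-Carlo approximation would be "
            "needed for tables this large"
        )
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    # log of (prod r_i! * prod c_j!) / N!
    log_margins = (
        gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(total + 1)
    )
    log_p_obs = _log_table_prob(arr, log_margins)
    cutoff = log_p_obs + np.log1p(_TIE_TOL)

    n_rows, n_cols = arr.shape
    p_sum = 0.0
    work = np.zeros_like(arr)

    def fill_row(row: int, col_remaining: np.ndarray) -> None:
        nonlocal p_sum
        if row == n_rows - 1:
            # Last row is forced by the column remainders.
            work[row] = col_remaining
            candidate = work
            lp = _log_table_prob(candidate, log_margins)
            if lp <= cutoff:
                p_sum += float(np.exp(lp))
            return
        target = row_sums[row]

        def fill_cell(col: int, left: int) -> None:
            if col == n_cols - 1:
                if left <= col_remaining[col]:
                    work[row, col] = left
                    col_remaining_next = col_remaining.copy()
                    col_remaining_next -= work[row]
                    fill_row(row + 1, col_remaining_next)
                return
            for v in range(min(left, col_remaining[col]) + 1):
                work[row, col] = v
                fill_cell(col + 1, left - v)

        fill_cell(0, int(target))

    fill_row(0, col_sums.copy())
    return min(1.0, p_sum)


@dataclass(frozen=True)
class RankSumResult:
    pvalue: float
    method: str
    statistic: float


def wilcoxon_rank_sum(x, y) -> RankSumResult:
    """Two-sided rank-sum test; exact when min(n) <= 25 and tie-free."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return RankSumResult(1.0, "degenerate", float("nan"))
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 25 and not has_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(float(res.pvalue), "exact", float(res.statistic))
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(float(res.pvalue), "normal-approx", float(res.statistic))


# ---------------------------------------------------------------------------
# Packaged cohort table (demographic categorical counts)
# ---------------------------------------------------------------------------

def load_cohort_table(path: str | Path | None = None) -> pd.DataFrame:
    """Categorical demographic counts per study group (packaged fixture)."""
    if path is None:
        with resources.as_file(
            resources.files("plasmeta.data").joinpath("cohort_table1.tsv")
        ) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def cohort_fisher_pvalues(
    table: pd.DataFrame | None = None,
    reference: str = "Healthy",
    comparisons: tuple[str, ...] = ("SLE", "CFS", "ADCLS"),
) -> pd.DataFrame:
    """Fisher exact p-values of each group vs the reference, per variable."""
    if table is None:
        table = load_cohort_table()
    rows = []
    for variable, sub in table.groupby("variable", sort=False):
        for group in comparisons:
            counts = sub[[reference, group]].to_numpy()
            p = fisher_exact(
                ContingencyTable.from_array(
                    counts, row_labels=tuple(sub["level"]),
                    col_labels=(reference, group),
                )
            )
            rows.append({"variable": variable, "comparison": f"{group} vs {reference}",
                         "p": p})
    return pd.DataFrame(rows)


__all__ = [
    "ContingencyTable",
    "RankSumResult",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "load_cohort_table",
    "cohort_fisher_pvalues",
    "ENUMERATION_GUARD",
]
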