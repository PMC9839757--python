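"""Cell-fate classification and stratified population statistics.

Fate categories follow the Pax7/MyoD positivity scheme: stem (Pax7+MyoD-),
progenitor (Pax7+MyoD+), committed (Pax7-MyoD+) and double negative.
Per-category differences between conditions are tested with the two-sided
Cochran-Mantel-Haenszel chi-square on 2x2xK tables, one stratum per
experimental repeat, pooling the "overall fraction" across repeats exactly
as counts.  Gene-list overlaps are scored with the one-tailed Fisher exact
(hypergeometric enrichment) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from .errors import NicheMechError

__all__ = [
    "CATEGORIES",
    "FateCall",
    "FateTable",
    "CMHResult",
    "OverlapTest",
    "classify_fate",
    "cmh_test",
    "cmh_test_category",
    "fisher_overlap",
]

CATEGORIES = ("stem", "progenitor", "committed", "double_negative")


@dataclass(frozen=True)
class FateCall:
    cell_id: object
    pax7_positive: bool
    myod_positive: bool

    @property
    def category(self) -> str:
        if self.pax7_positive:
            return "stem" if not self.myod_positive else "progenitor"
        return "committed" if self.myod_positive else "double_negative"


@dataclass(frozen=True)
class CMHResult:
    statistic: float
    p_value: float
    strata_used: int


@dataclass(frozen=True)
class OverlapTest:
    universe_size: int
    list_a_size: int
    list_b_size: int
    overlap_k: int
    p_value: float


def classify_fate(levels: dict, cutoffs: dict, cell_id=None) -> FateCall:
    """Positivity calls from calibrated per-channel cutoffs.

    ``levels`` and ``cutoffs`` must both contain ``"pax7"`` and ``"myod"``.
    Positivity is strict (``level > cutoff``): a level exactly at the cutoff
    is negative.
    """
    for key in ("pax7", "myod"):
        if key not in levels or key not in cutoffs:
            raise NicheMechError(f"missing channel '{key}'")
    return FateCall(
        cell_id=cell_id,
        pax7_positive=cutoffs["pax7"].is_positive(levels["pax7"]),
        myod_positive=cutoffs["myod"].is_positive(levels["myod"]),
    )


class FateTable:
    """Per-repeat, per-condition category counts.

    Backed by a DataFrame with columns (condition, repeat, category, count).
    """

    def __init__(self, counts: pd.DataFrame):
        required = {"condition", "repeat", "category", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts must have columns {sorted(required)}")
        if (counts["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.copy()

    @classmethod
    def from_calls(cls, calls, condition, repeat) -> "FateTable":
        rows = pd.DataFrame({
            "condition": condition,
            "repeat": repeat,
            "category": [c.category for c in calls],
        })
        counts = (rows.value_counts().rename("count").reset_index())
        return cls(counts)

    def overall_fractions(self, condition) -> pd.Series:
        """Pooled fractions: total category count / total cells, all repeats."""
        sub = self.counts[self.counts["condition"] == condition]
        by_cat = sub.groupby("category")["count"].sum()
        by_cat = by_cat.reindex(CATEGORIES, fill_value=0)
        total = by_cat.sum()
        if total == 0:
            raise NicheMechError(f"no cells for condition '{condition}'")
        return by_cat / total

    def strata_2x2(self, condition_a, condition_b, category) -> np.ndarray:
        """2x2 tables (category vs rest x condition), one per shared repeat."""
        tabs = []
        df = self.counts
        reps = sorted(set(df.loc[df.condition == condition_a, "repeat"])
                      & set(df.loc[df.condition == condition_b, "repeat"]))
        for rep in reps:
            tab = np.zeros((2, 2))
            for j, cond in enumerate((condition_a, condition_b)):
                sub = df[(df.condition == cond) & (df["repeat"] == rep)]
                in_cat = sub.loc[sub.category == category, "count"].sum()
                total = sub["count"].sum()
                tab[0, j] = in_cat
                tab[1, j] = total - in_cat
            tabs.append(tab)
        return np.array(tabs)


def cmh_test(tables) -> CMHResult:
    """Cochran-Mantel-Haenszel chi-square test on stratified 2x2 tables.

    ``tables`` has shape (K, 2, 2), one stratum per experimental repeat.
    No continuity correction is applied; the 1-df chi-square upper tail is
    inherently two-sided for the common odds ratio.  Strata with a zero
    margin carry no information and are dropped with a warning.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim == 2:
        tables = tables[None]
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (K, 2, 2)")
    keep = []
    for tab in tables:
        margins_ok = tab.sum(0).min() > 0 and tab.sum(1).min() > 0 and tab.sum() > 1
        if margins_ok:
            keep.append(tab)
        else:
            warnings.warn("dropping degenerate stratum (zero margin)", stacklevel=2)
    if not keep:
        raise NicheMechError("all strata degenerate: CMH test undefined")
    st = StratifiedTable(np.transpose(np.array(keep), (1, 2, 0)))
    res = st.test_null_odds(correction=False)
    return CMHResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                     strata_used=len(keep))


def cmh_test_category(table: FateTable, condition_a, condition_b, category) -> CMHResult:
    """CMH test of one fate category (vs the rest) between two conditions."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category '{category}'")
    return cmh_test(table.strata_2x2(condition_a, condition_b, category))


def fisher_overlap(universe_size: int, list_a_size: int, list_b_size: int,
                   overlap_k: int) -> OverlapTest:
    """Fisher exact (hypergeometric upper tail) gene-list overlap test.

    ``p = P(X >= k)`` for ``X ~ Hypergeom(N, a, b)``: the probability of an
    overlap at least as large as observed when list b is drawn at random
    from the universe.
    """
    N, a, b, k = universe_size, list_a_size, list_b_size, overlap_k
    if not (0 <= a <= N and 0 <= b <= N):
        raise ValueError("list sizes must lie within the universe")
    if not 0 <= k <= min(a, b):
        raise ValueError("overlap must not exceed the smaller list")
    p = float(sps.hypergeom.sf(k - 1, N, a, b))
    return OverlapTest(universe_size=N, list_a_size=a, list_b_size=b,
                       overlap_k=k, p_value=min(p, 1.0))
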