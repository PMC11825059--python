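"""Classifier-comparison statistics over per-dataset accuracy tables.

Accuracy, pairwise win/tie/loss counts, the tie-corrected Friedman
omnibus test, and pairwise two-sided Wilcoxon signed-rank tests with
Holm's step-down correction, including the "cliques" of mutually
non-distinguished methods that critical-difference diagrams draw as
solid bars.  Missing cells (a method that ran out of memory on a
dataset) drop the affected rows from omnibus tests and from pairwise
comparisons that involve that method only; every exclusion is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["AccuracyTable", "accuracy", "pairwise_wins", "friedman_test",
           "wilcoxon_holm", "load_packaged_table"]


def accuracy(y_true, y_pred) -> float:
    """Fraction of exact label matches ((TP+TN)/total in the binary case)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    return float((y_true == y_pred).mean())


@dataclass
class AccuracyTable:
    """Datasets x methods accuracy matrix; NaN marks a missing cell."""

    datasets: list[str]
    methods: list[str]
    acc: np.ndarray  # (n_datasets, n_methods), values in [0, 1] or NaN

    def __post_init__(self):
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.shape != (len(self.datasets), len(self.methods)):
            raise ValueError("acc shape must be (n_datasets, n_methods)")
        finite = self.acc[np.isfinite(self.acc)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "AccuracyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def column(self, method: str) -> np.ndarray:
        if method not in self.methods:
            raise KeyError(f"unknown method {method!r}")
        return self.acc[:, self.methods.index(method)]

    def complete_rows(self, methods: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """(row mask, excluded dataset names) over the chosen columns."""
        cols = [self.methods.index(m) for m in (methods or self.methods)]
        ok = np.isfinite(self.acc[:, cols]).all(axis=1)
        return ok, [d for d, keep in zip(self.datasets, ok) if not keep]


def load_packaged_table(name: str) -> AccuracyTable:
    """Tables shipped with the package: 'uea' (9 methods x 29 datasets)
    or 'ablation' (with/without contrastive pre-training)."""
    from importlib.resources import files

    fname = {"uea": "uea_accuracy.csv", "ablation": "ablation_accuracy.csv"}[name]
    return AccuracyTable.from_csv(files("supcon_tsc.data") / fname)


def pairwise_wins(table: AccuracyTable, method_a: str, method_b: str
                  ) -> tuple[int, int, int]:
    """(wins, ties, losses) of a over b; rows missing either cell excluded.

    Ties are exact equality of the recorded values.  The conventional
    "outperforms on k of n datasets" headline counts wins plus ties.
    """
    a, b = table.column(method_a), table.column(method_b)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    return int((a > b).sum()), int((a == b).sum()), int((a < b).sum())


def _mid_ranks(row: np.ndarray) -> np.ndarray:
    """Rank 1 = best accuracy, ties get mid-ranks."""
    return sstats.rankdata(-row)


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: dict[str, float]
    excluded: list[str] = field(default_factory=list)


def friedman_test(table: AccuracyTable) -> FriedmanResult:
    """Tie-corrected Friedman chi-square over complete rows."""
    if len(table.methods) < 3:
        raise ValueError("Friedman test needs at least 3 methods")
    ok, excluded = table.complete_rows()
    acc = table.acc[ok]
    if acc.shape[0] < 2:
        raise ValueError("Friedman test needs at least 2 complete rows")
    ranks = np.vstack([_mid_ranks(row) for row in acc])
    mean_ranks = dict(zip(table.methods, ranks.mean(axis=0)))
    if np.allclose(ranks.var(axis=1), 0.0):  # every row fully tied
        return FriedmanResult(0.0, 1.0, mean_ranks, excluded)
    stat, p = sstats.friedmanchisquare(*acc.T)
    return FriedmanResult(float(stat), float(p), mean_ranks, excluded)


@dataclass
class WilcoxonHolmResult:
    p_values: pd.DataFrame  # raw two-sided p per pair (symmetric)
    holm_reject: pd.DataFrame  # Holm-adjusted decisions (True = different)
    mean_ranks: dict[str, float]
    cliques: list[list[str]]
    excluded: dict[tuple[str, str], list[str]] = field(default_factory=dict)


def _pair_p(a: np.ndarray, b: np.ndarray, zero_method: str) -> float:
    d = a - b
    if np.all(d == 0):
        return 1.0
    try:
        return float(sstats.wilcoxon(a, b, zero_method=zero_method,
                                     alternative="two-sided").pvalue)
    except ValueError:
        return 1.0


def wilcoxon_holm(table: AccuracyTable, alpha: float = 0.05,
                  zero_method: str = "wilcox") -> WilcoxonHolmResult:
    """Pairwise Wilcoxon signed-rank with Holm correction and rank cliques.

    ``zero_method`` 'wilcox' drops zero differences (default); 'pratt'
    keeps them in the ranking.  Cliques are maximal groups, contiguous in
    mean-rank order, whose pairs are all non-rejected — the solid bars of
    a critical-difference diagram.
    """
    methods = table.methods
    m = len(methods)
    if m < 2:
        raise ValueError("need at least 2 methods")
    ok_all, _ = table.complete_rows()
    ranks = np.vstack([_mid_ranks(row) for row in table.acc[ok_all]])
    mean_ranks = dict(zip(methods, ranks.mean(axis=0)))

    pmat = np.full((m, m), np.nan)
    excluded: dict[tuple[str, str], list[str]] = {}
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            a, b = table.acc[:, i], table.acc[:, j]
            ok = np.isfinite(a) & np.isfinite(b)
            dropped = [d for d, keep in zip(table.datasets, ok) if not keep]
            if dropped:
                excluded[(methods[i], methods[j])] = dropped
            p = _pair_p(a[ok], b[ok], zero_method)
            pmat[i, j] = pmat[j, i] = p
            pairs.append((p, i, j))

    # Holm step-down over the m(m-1)/2 raw p-values
    reject = np.zeros((m, m), dtype=bool)
    pairs.sort(key=lambda t: t[0])
    k = len(pairs)
    for rank, (p, i, j) in enumerate(pairs):
        if p <= alpha / (k - rank):
            reject[i, j] = reject[j, i] = True
        else:
            break  # Holm stops at the first non-rejection

    order = sorted(range(m), key=lambda i: ranks.mean(axis=0)[i])
    cliques: list[list[str]] = []
    for start in range(m):
        end = start
        while end + 1 < m and not any(
                reject[order[a], order[b]]
                for a in range(start, end + 2) for b in range(a + 1, end + 2)):
            end += 1
        group = [methods[order[i]] for i in range(start, end + 1)]
        if not any(set(group) <= set(g) for g in cliques):
            cliques.append(group)

    idx = pd.Index(methods)
    return WilcoxonHolmResult(
        p_values=pd.DataFrame(pmat, index=idx, columns=idx),
        holm_reject=pd.DataFrame(reject, index=idx, columns=idx),
        mean_ranks=mean_ranks, cliques=cliques, excluded=excluded)
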