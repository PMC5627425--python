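"""Clustering evaluation: adjusted Rand index, precision, recall.

All three are computed from the contingency table of a predicted partition
against a reference partition.  The ARI is chance-corrected pair-counting
agreement (1 = identical, ~0 = random, negative possible); precision is the
accuracy under the most favorable assignment of a species label to each
predicted cluster; recall measures how well the best single cluster regroups
each species.

Binomial sums are accumulated in exact integer/rational arithmetic
(``fractions.Fraction``) — at large N the numerator of the ARI is a small
difference of huge terms, where floating point cancels catastrophically.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

__all__ = [
    "ContingencyTable",
    "contingency",
    "adjusted_rand_index",
    "precision",
    "recall",
    "evaluate_binning",
]


@dataclass
class ContingencyTable:
    """Cross-tabulation of two partitions of the same N items."""

    n: np.ndarray  # (r, s) counts, n[i, j] = |pred cluster i ∩ true cluster j|
    pred_labels: list
    true_labels: list

    @property
    def row_sums(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.n.sum())


def contingency(pred, truth) -> ContingencyTable:
    """Exact cross-tabulation; label values may be any hashables."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError(
            f"label vectors differ in length: {len(pred)} vs {len(truth)}"
        )
    if len(pred) < 2:
        raise ValueError("need at least 2 items to compare partitions")
    pl = sorted(set(pred), key=lambda x: (str(type(x)), str(x)))
    tl = sorted(set(truth), key=lambda x: (str(type(x)), str(x)))
    pi = {lab: i for i, lab in enumerate(pl)}
    ti = {lab: j for j, lab in enumerate(tl)}
    n = np.zeros((len(pl), len(tl)), dtype=np.int64)
    for a, b in zip(pred, truth):
        n[pi[a], ti[b]] += 1
    return ContingencyTable(n=n, pred_labels=pl, true_labels=tl)


def _as_table(pred, truth=None) -> ContingencyTable:
    if isinstance(pred, ContingencyTable):
        return pred
    if truth is None:
        raise ValueError("pass a ContingencyTable or two label vectors")
    return contingency(pred, truth)


def adjusted_rand_index(table, truth=None) -> float:
    """Chance-corrected Rand index from a contingency table (exact arithmetic).

    ARI = (sum_ij C(n_ij,2) - E) / (0.5*[sum_i C(r_i,2) + sum_j C(c_j,2)] - E)
    with E = sum_i C(r_i,2) * sum_j C(c_j,2) / C(N,2).

    When both partitions are trivial (each a single cluster, or all
    singletons) the denominator is 0; the two partitions are then identical
    and the ARI is defined as 1.  A zero denominator with *different*
    partitions cannot occur.
    """
    t = _as_table(table, truth)
    N = t.total
    if N < 2:
        raise ValueError("ARI needs at least 2 items")
    sum_ij = sum(comb(int(v), 2) for v in t.n.ravel())
    sum_r = sum(comb(int(v), 2) for v in t.row_sums)
    sum_c = sum(comb(int(v), 2) for v in t.col_sums)
    expected = Fraction(sum_r * sum_c, comb(N, 2))
    denom = Fraction(sum_r + sum_c, 2) - expected
    if denom == 0:
        return 1.0
    return float((sum_ij - expected) / denom)


def precision(table, truth=None) -> float:
    """sum_i max_j n_ij / N: purity of predicted clusters w.r.t. the truth."""
    t = _as_table(table, truth)
    return float(t.n.max(axis=1).sum() / t.total)


def recall(table, truth=None) -> float:
    """sum_j max_i n_ij / N: completeness of the best cluster per species."""
    t = _as_table(table, truth)
    return float(t.n.max(axis=0).sum() / t.total)


def evaluate_binning(pred, truth) -> dict[str, float]:
    """ARI, precision, and recall of a predicted labeling against truth."""
    t = contingency(pred, truth)
    return {
        "ari": adjusted_rand_index(t),
        "precision": precision(t),
        "recall": recall(t),
    }
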