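"""EM starting values from hierarchical clustering of high-count contigs.

EM is only locally convergent, so the starting point matters.  The strategy:
take the 10-30% of contigs with the most mapped reads (their sample profiles
are the least noisy), agglomerate them under the cosine distance — which is
scale-invariant, so it compares profiles, not depths — cut the tree at K
clusters, and use cluster means of the row-normalized count vectors as the
initial species profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .io import CountMatrix
from .mixture import MixtureParams, _as_counts

__all__ = ["InitConfig", "cosine_distance", "hclust_init", "perturbed_inits"]

_LINKAGES = {"average", "complete", "ward"}


@dataclass
class InitConfig:
    """Initialization settings: top-count fraction, linkage, restart count."""

    top_fraction: float = 0.2
    linkage: str = "average"
    restarts: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0.10 <= self.top_fraction <= 0.30:
            warnings.warn(
                f"top_fraction={self.top_fraction} is outside the conventional "
                "0.10-0.30 range",
                UserWarning,
            )
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")


def cosine_distance(x1: np.ndarray, x2: np.ndarray) -> float:
    """1 - cos(x1, x2): scale-invariant dissimilarity of two count vectors.

    Zero for proportional vectors, one for vectors with disjoint support.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.sqrt(x1 @ x1)
    n2 = np.sqrt(x2 @ x2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine distance undefined for an all-zero vector")
    return float(1.0 - (x1 @ x2) / (n1 * n2))


def _select_top(X: np.ndarray, top_fraction: float, k: int) -> np.ndarray:
    """Indices of the highest-count rows; stable order, ties by row order."""
    n = X.shape[0]
    m = max(int(np.ceil(top_fraction * n)), k)
    if m > n:
        raise ValueError(
            f"K={k} exceeds the {n} available contigs; increase top_fraction "
            "or provide more contigs"
        )
    totals = X.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    return np.sort(order[:m])


def _params_from_partition(
    X: np.ndarray, members: list[np.ndarray]
) -> MixtureParams:
    norm = X / X.sum(axis=1, keepdims=True)
    k = len(members)
    p = X.shape[1]
    A = np.empty((k, p))
    pi = np.empty(k)
    total = sum(len(m) for m in members)
    for kk, idx in enumerate(members):
        prof = norm[idx].mean(axis=0) + 1e-10
        A[kk] = prof / prof.sum()
        pi[kk] = len(idx) / total
    return MixtureParams(pi, A)


def hclust_init(
    X,
    k: int,
    *,
    top_fraction: float = 0.2,
    linkage: str = "average",
) -> MixtureParams:
    """Deterministic starting parameters for a K-component mixture fit.

    Profiles are cluster means of row-normalized counts (so deep contigs do
    not dominate), renormalized to the simplex; weights are cluster sizes
    over the number of selected contigs.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    X = _as_counts(X).astype(float)
    sel = _select_top(X, top_fraction, k)
    sub = X[sel]
    if k == 1:
        members = [np.arange(len(sel))]
    else:
        if linkage == "ward":
            normed = sub / sub.sum(axis=1, keepdims=True)
            Z = scipy_linkage(normed, method="ward")
        else:
            d = pdist(sub, metric="cosine")
            Z = scipy_linkage(d, method=linkage)
        assign = fcluster(Z, t=k, criterion="maxclust")
        labels = np.unique(assign)
        if len(labels) < k:
            raise ValueError(
                f"hierarchical clustering produced {len(labels)} < {k} "
                "clusters; the selected contigs may contain duplicates"
            )
        members = [np.flatnonzero(assign == lab) for lab in labels]
    return _params_from_partition(sub, members)


def perturbed_inits(
    X,
    k: int,
    n_restarts: int,
    rng: np.random.Generator,
    *,
    top_fraction: float = 0.2,
    linkage: str = "average",
):
    """Yield alternative starts by bootstrapping the selected contig subset.

    Each restart re-selects (with replacement) among the top-count contigs and
    re-clusters, giving EM different basins to explore; the caller keeps the
    best final log-likelihood.
    """
    X = _as_counts(X).astype(float)
    sel = _select_top(X, top_fraction, k)
    for _ in range(n_restarts):
        boot = rng.choice(sel, size=len(sel), replace=True)
        boot = np.unique(boot)
        if len(boot) < k:
            extra = rng.choice(sel, size=k - len(boot) + 1, replace=False)
            boot = np.unique(np.concatenate([boot, extra]))
        sub = X[boot]
        if linkage == "ward":
            normed = sub / sub.sum(axis=1, keepdims=True)
            Z = scipy_linkage(normed, method="ward")
        else:
            Z = scipy_linkage(pdist(sub, metric="cosine"), method=linkage)
        assign = fcluster(Z, t=k, criterion="maxclust")
        labels = np.unique(assign)
        if len(labels) < k:
            continue
        members = [np.flatnonzero(assign == lab) for lab in labels]
        yield _params_from_partition(sub, members)
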