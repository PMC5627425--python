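"""Non-negative matrix factorization view of the binning problem.

If noise were negligible, the count matrix would factor exactly as
``X = M @ E``: ``M[i, k]`` is the number of reads one copy of contig ``i``
yields when it belongs to species ``k`` (zero otherwise), and ``E[k, j]`` is
the total abundance of species ``k`` in sample ``j``.  Row-normalizing ``E``
recovers the sample-profile matrix ``A`` (``E = D @ A``).  Minimizing
``||X - M E||_F`` with multiplicative (Lee-Seung) updates therefore gives an
independent, likelihood-free route to the same bins and profiles, useful as
a cross-check on the EM fit.  It offers no principled way to choose K, so it
is a diagnostic, not the primary fit path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .mixture import _as_counts

__all__ = ["NMFResult", "nmf_factorize", "nmf_labels", "CountNMF"]

_EPS = 1e-12

UNASSIGNED = -1


@dataclass
class NMFResult:
    """Factors and diagnostics of one NMF run."""

    M: np.ndarray  # (N, K) signature matrix, >= 0
    E: np.ndarray  # (K, P) total abundance matrix, >= 0
    residual: float  # ||X - M E||_F at termination
    residual_trace: np.ndarray  # per-iteration Frobenius residuals
    n_iter: int
    converged: bool

    @property
    def profiles(self) -> np.ndarray:
        """Row-normalized E — the sample-profile matrix A (rows on the simplex)."""
        sums = self.E.sum(axis=1, keepdims=True)
        out = np.zeros_like(self.E)
        pos = sums[:, 0] > 0
        out[pos] = self.E[pos] / sums[pos]
        return out


def nmf_factorize(
    X,
    K: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NMFResult:
    """Factor X ~= M @ E by multiplicative updates on the Frobenius objective.

    Both factors start from seeded uniform(0, 1] draws scaled so that the
    initial product matches X's mean.  The Lee-Seung updates never increase
    the residual; iteration stops when its relative change drops below
    ``tol``.
    """
    X = _as_counts(X).astype(float)
    n, p = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(n, p):
        raise ValueError(f"K={K} exceeds min(N, P)={min(n, p)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / K)
    M = scale * (1.0 - rng.random((n, K)))  # uniform (0, 1], avoids exact zeros
    E = scale * (1.0 - rng.random((K, p)))
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # H-update then W-update, each a monotone descent step
        E *= (M.T @ X) / (M.T @ M @ E + _EPS)
        M *= (X @ E.T) / (M @ (E @ E.T) + _EPS)
        resid = float(np.linalg.norm(X - M @ E))
        trace.append(resid)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(prev - resid) <= tol * (prev + _EPS):
                converged = True
                break
    return NMFResult(
        M=M,
        E=E,
        residual=trace[-1],
        residual_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
    )


def nmf_labels(result: NMFResult) -> np.ndarray:
    """Hard bin per contig: argmax over signature columns, lowest index on ties.

    A contig whose signature row is entirely zero cannot be attributed to any
    component and gets the ``UNASSIGNED`` (-1) sentinel.
    """
    labels = np.argmax(result.M, axis=1)
    labels[result.M.sum(axis=1) == 0] = UNASSIGNED
    return labels


class CountNMF(TransformerMixin, BaseEstimator):
    """Estimator wrapper around :func:`nmf_factorize`.

    Attributes (after fit): ``signatures_`` (M), ``totals_`` (E),
    ``profiles_`` (row-normalized E), ``labels_``, ``residual_``,
    ``residual_trace_``, ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        *,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        result = nmf_factorize(
            X,
            self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        self.signatures_ = result.M
        self.totals_ = result.E
        self.profiles_ = result.profiles
        self.labels_ = nmf_labels(result)
        self.residual_ = result.residual
        self.residual_trace_ = result.residual_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.result_ = result
        return self

    def transform(self, X):
        """Project count rows onto the fitted profiles (NNLS per row)."""
        check_is_fitted(self, "totals_")
        from scipy.optimize import nnls

        X = _as_counts(X).astype(float)
        out = np.empty((X.shape[0], self.totals_.shape[0]))
        for i, row in enumerate(X):
            out[i], _ = nnls(self.totals_.T, row)
        return out

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.signatures_
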