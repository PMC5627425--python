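"""Multinomial mixture model over contig sample profiles, fit by EM.

Model
-----
Each contig ``i`` carries a latent species label ``z_i`` with
``P(z_i = k) = pi_k``; given ``z_i = k`` its cross-sample read-count vector
``x_i`` (length P, total ``n_i``) is Multinomial(``n_i``, ``a_k``), where
``a_k`` is the species' *sample profile* — the proportion of its reads
contributed by each sample.  Maximum likelihood in ``theta = (pi, A)`` is
found by EM.  The multinomial coefficient is constant in both ``k`` and
``theta`` and is dropped from every likelihood expression here; absolute
log-likelihood values are therefore not comparable across implementations
that keep it, but all differences (across iterations, across K, in BIC) are
unaffected.

All E-step arithmetic is in log space with log-sum-exp: literal products
``a_kj ** x_ij`` underflow for realistic read totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix

__all__ = [
    "MixtureParams",
    "FitResult",
    "log_component_weight",
    "e_step",
    "m_step",
    "observed_loglik",
    "fit_em",
    "MultinomialMixtureBinner",
]

_SIMPLEX_TOL = 1e-10


@dataclass
class MixtureParams:
    """Mixing weights ``pi`` (K,) and sample-profile matrix ``A`` (K, P).

    ``pi`` and every row of ``A`` lie on the probability simplex.
    """

    pi: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.pi.ndim != 1 or self.A.ndim != 2 or self.A.shape[0] != self.pi.shape[0]:
            raise ValueError("pi must be (K,), A must be (K, P)")
        if (self.pi < 0).any() or (self.A < 0).any():
            raise ValueError("mixture parameters must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"pi sums to {self.pi.sum()}, expected 1")
        rows = self.A.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-8:
            raise ValueError("rows of A must sum to 1")
        # renormalize away float dust so invariants hold to 1e-10
        self.pi = self.pi / self.pi.sum()
        self.A = self.A / rows[:, None]

    @property
    def n_components(self) -> int:
        return self.pi.shape[0]

    def permuted(self, order: np.ndarray) -> "MixtureParams":
        """Return a copy with components relabeled by ``order``."""
        order = np.asarray(order)
        return MixtureParams(self.pi[order], self.A[order])


@dataclass
class FitResult:
    """Outcome of one EM fit at fixed K."""

    params: MixtureParams
    posterior: np.ndarray  # (N, K) responsibilities, rows on the simplex
    labels: np.ndarray  # (N,) hard assignments, argmax of posterior
    loglik_trace: np.ndarray  # observed-data log-likelihood per iteration
    converged: bool
    n_iter: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _as_counts(x) -> np.ndarray:
    if isinstance(x, CountMatrix):
        return x.counts
    return np.asarray(x)


def log_component_weight(x: np.ndarray, a: np.ndarray, pi_k: float) -> float:
    """log pi_k + sum_j x_j log a_kj for one contig and one component.

    Returns ``-inf`` (never raises) when the component's profile is zero in a
    sample where the contig has reads — the component cannot have generated
    the contig.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.sum() <= 0:
        raise ValueError("contig must have at least one mapped read")
    if ((a == 0) & (x > 0)).any():
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.where(a > 0, a, 1.0)), 0.0)
    return float(np.log(pi_k) + terms.sum()) if pi_k > 0 else float("-inf")


def _log_scores(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(N, K) matrix of log pi_k + sum_j x_ij log a_kj, -inf where impossible."""
    X = np.asarray(X, dtype=float)
    A, pi = params.A, params.pi
    logA = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), 0.0)
    S = X @ logA.T
    with np.errstate(divide="ignore"):
        S = S + np.log(pi)[None, :]
    impossible = (X > 0) @ (A == 0).T.astype(float) > 0
    S[impossible] = -np.inf
    return S


def e_step(X, params: MixtureParams) -> np.ndarray:
    """Posterior responsibilities q_ik, rows renormalized exactly to 1.

    Bayes' rule per contig, computed in log space with log-sum-exp.
    """
    X = _as_counts(X)
    S = _log_scores(X, params)
    norm = logsumexp(S, axis=1)
    dead = ~np.isfinite(norm)
    if dead.any():
        raise ValueError(
            "no component can generate contig rows "
            f"{np.flatnonzero(dead).tolist()[:10]} (all scores -inf)"
        )
    q = np.exp(S - norm[:, None])
    return q / q.sum(axis=1, keepdims=True)


def m_step(X, posterior: np.ndarray, *, smoothing: float = 1e-10) -> MixtureParams:
    """Maximization update: pi_k ∝ Σ_i q_ik, a_kj ∝ smoothing + Σ_i q_ik x_ij.

    The pseudo-count keeps every profile entry positive so no later E-step
    score is -inf merely because a species drew no reads in one sample.
    A component with essentially zero responsibility mass (Σ_i q_ik < 1e-12)
    has no data to define its profile; instead of returning NaN, its profile
    is re-seeded with the empirical profile of the contig the current model
    fits worst (lowest max posterior).  Its weight stays ∝ Σ_i q_ik as the
    update dictates; K is never reduced here — the selection loop owns K.
    """
    X = _as_counts(X).astype(float)
    q = np.asarray(posterior, dtype=float)
    mass = q.sum(axis=0)
    num = q.T @ X + smoothing
    empty = mass < 1e-12
    if empty.any():
        worst = int(np.argmin(q.max(axis=1)))
        num[empty] = X[worst] + max(smoothing, 1e-300)
    A = num / num.sum(axis=1, keepdims=True)
    pi = mass / mass.sum()
    return MixtureParams(pi, A)


def observed_loglik(X, params: MixtureParams) -> float:
    """Observed-data log-likelihood Σ_i log Σ_k exp(score_ik).

    Multinomial coefficients are omitted (see module docstring).  An -inf
    result is returned as a sentinel with a warning listing offending rows.
    """
    X = _as_counts(X)
    S = _log_scores(X, params)
    per_row = logsumexp(S, axis=1)
    bad = ~np.isfinite(per_row)
    if bad.any():
        warnings.warn(
            "log-likelihood is -inf: contig rows "
            f"{np.flatnonzero(bad).tolist()[:10]} have zero probability "
            "under every component",
            RuntimeWarning,
        )
        return float("-inf")
    return float(per_row.sum())


def fit_em(
    X,
    init: MixtureParams,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    smoothing: float = 1e-10,
) -> FitResult:
    """Run EM to convergence from the given starting parameters.

    Alternates :func:`e_step` / :func:`m_step` until the relative change of
    the observed-data log-likelihood falls below ``tol`` or ``max_iter`` is
    reached.  Hard labels are the row-wise posterior argmax with
    lowest-index tie-break (numpy argmax semantics).
    """
    Xc = _as_counts(X)
    n = Xc.shape[0]
    K = init.n_components
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of contigs N={n}")
    params = init
    trace: list[float] = []
    converged = False
    q = e_step(Xc, params)
    for it in range(max_iter):
        params = m_step(Xc, q, smoothing=smoothing)
        ll = observed_loglik(Xc, params)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite log-likelihood at iteration {it}"
            )
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) <= tol * (abs(prev) + 1e-300):
                converged = True
                break
        q = e_step(Xc, params)
    q = e_step(Xc, params)
    return FitResult(
        params=params,
        posterior=q,
        labels=np.argmax(q, axis=1),
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
    )


class MultinomialMixtureBinner(ClusterMixin, BaseEstimator):
    """Cluster contigs into species bins from their cross-sample read counts.

    Fits a K-component multinomial mixture to an ``(N, P)`` integer count
    matrix by EM, starting from a hierarchical clustering of the
    highest-count contigs.  When ``n_components`` is None the number of bins
    is chosen by BIC over an increasing scan of K.

    Parameters
    ----------
    n_components : int or None, default=None
        Number of species bins K.  None triggers BIC model selection between
        ``k_min`` and ``k_max``.
    top_fraction : float, default=0.2
        Fraction of highest-count contigs used for the hierarchical-clustering
        initialization (conventionally 0.10–0.30).
    linkage : {"average", "complete", "ward"}, default="average"
        Linkage for the initialization tree.  "ward" operates on
        row-normalized profiles with Euclidean distance; the others use the
        cosine distance on raw counts.
    smoothing : float, default=1e-10
        Pseudo-count added to every profile entry in the M-step.
    tol : float, default=1e-6
        Relative log-likelihood change declaring EM convergence.
    max_iter : int, default=500
        EM iteration cap per candidate K.
    n_restarts : int, default=0
        Extra EM runs from perturbed initializations; the best final
        log-likelihood wins.  0 keeps the single deterministic start.
    k_min, k_step, k_max : int, model-selection scan bounds (used only when
        ``n_components`` is None); ``k_max`` of None scans until the BIC turns
        upward.
    random_state : int or None
        Seed for restart perturbations (the default fit path is
        deterministic).

    Attributes
    ----------
    n_components_ : int
        Number of bins in the fitted model (selected by BIC if requested).
    weights_ : ndarray (K,)
        Mixing weights pi.
    profiles_ : ndarray (K, P)
        Species sample-profile matrix A; rows on the simplex.
    responsibilities_ : ndarray (N, K)
        Posterior membership probabilities.
    labels_ : ndarray (N,)
        Hard bin assignment per contig.
    loglik_trace_ : ndarray
        Observed-data log-likelihood per EM iteration of the final fit.
    bic_ : float
        BIC score of the final fit.
    selection_ : SelectionTrace or None
        Full scan record when model selection ran.
    converged_ : bool, n_iter_ : int
        EM convergence metadata.

    Examples
    --------
    >>> from profilebin import simulate_community, SimConfig
    >>> cm, truth = simulate_community(SimConfig(K=3, P=8, N=200, seed=0))
    >>> est = MultinomialMixtureBinner(n_components=3).fit(cm.counts)
    >>> est.profiles_.shape
    (3, 8)
    """

    def __init__(
        self,
        n_components: int | None = None,
        *,
        top_fraction: float = 0.2,
        linkage: str = "average",
        smoothing: float = 1e-10,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 0,
        k_min: int = 1,
        k_step: int = 1,
        k_max: int | None = None,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.top_fraction = top_fraction
        self.linkage = linkage
        self.smoothing = smoothing
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.k_min = k_min
        self.k_step = k_step
        self.k_max = k_max
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _fit_single(self, X: np.ndarray, k: int) -> FitResult:
        from .initialization import hclust_init, perturbed_inits

        init = hclust_init(
            X, k, top_fraction=self.top_fraction, linkage=self.linkage
        )
        best = fit_em(
            X, init, tol=self.tol, max_iter=self.max_iter, smoothing=self.smoothing
        )
        if self.n_restarts > 0:
            rng = np.random.default_rng(self.random_state)
            for alt in perturbed_inits(
                X, k, self.n_restarts, rng,
                top_fraction=self.top_fraction, linkage=self.linkage,
            ):
                cand = fit_em(
                    X, alt, tol=self.tol, max_iter=self.max_iter,
                    smoothing=self.smoothing,
                )
                if cand.loglik > best.loglik:
                    best = cand
        return best

    def fit(self, X, y=None):
        """Fit the mixture to an (N, P) count matrix or CountMatrix."""
        from .selection import bic_score, select_k

        Xc = _as_counts(X)
        if Xc.ndim != 2:
            raise ValueError("X must be a 2-D count matrix")
        if (Xc < 0).any():
            raise ValueError("counts must be non-negative")
        if (Xc.sum(axis=1) == 0).any():
            raise ValueError(
                "every contig row must have at least one mapped read; "
                "use filter_contigs first"
            )
        n, p = Xc.shape
        if self.n_components is None:
            trace = select_k(
                Xc,
                k_min=self.k_min,
                k_step=self.k_step,
                k_max=self.k_max,
                fit_fn=self._fit_single,
            )
            self.selection_ = trace
            result = trace.best_fit
            self.n_components_ = trace.chosen_K
        else:
            self.selection_ = None
            self.n_components_ = int(self.n_components)
            result = self._fit_single(Xc, self.n_components_)
        self.weights_ = result.params.pi
        self.profiles_ = result.params.A
        self.responsibilities_ = result.posterior
        self.labels_ = result.labels
        self.loglik_trace_ = result.loglik_trace
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.bic_ = bic_score(result.loglik, self.n_components_, p, n)
        self.result_ = result
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior bin membership for new count rows."""
        check_is_fitted(self, "profiles_")
        return e_step(_as_counts(X), MixtureParams(self.weights_, self.profiles_))

    def predict(self, X) -> np.ndarray:
        """Hard bin assignment for new count rows (posterior argmax)."""
        return np.argmax(self.predict_proba(X), axis=1)
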