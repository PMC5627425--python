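"""Choosing the number of species bins by BIC.

The mixture likelihood always improves as K grows; BIC trades that off
against a complexity penalty of ``(K*P + K) * log N`` — one parameter per
profile entry plus one mixing weight per component.  (A textbook count would
subtract the simplex constraints, giving ``(K-1) + K*(P-1)``; the
unconstrained count is used deliberately, and since the difference is
monotone in K it cannot change where the minimum falls relative to a fixed
convention.)  The search increases K from ``k_min`` and stops at the first
candidate whose BIC exceeds its predecessor; the chosen K minimizes BIC over
the evaluated candidates.

For communities with hundreds-to-thousands of species a step-1 scan is
impractical; ``select_k_geometric`` first doubles K until the BIC turns
upward, then refines linearly inside the bracket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mixture import FitResult

__all__ = ["SelectionTrace", "bic_score", "select_k", "select_k_geometric"]


def bic_score(loglik: float, K: int, P: int, N: int) -> float:
    """BIC(K) = -2*loglik + (K*P + K)*log(N), natural log; smaller is better."""
    if N < 1 or K < 1 or P < 1:
        raise ValueError("N, K, P must all be >= 1")
    return -2.0 * loglik + (K * P + K) * np.log(N)


@dataclass
class SelectionTrace:
    """Record of a BIC scan over candidate K values."""

    candidate_Ks: list[int] = field(default_factory=list)
    bic_scores: list[float] = field(default_factory=list)
    fits: list[FitResult] = field(default_factory=list)
    chosen_K: int = 0
    cap_reached: bool = False

    @property
    def best_fit(self) -> FitResult:
        idx = self.candidate_Ks.index(self.chosen_K)
        return self.fits[idx]


def _evaluate(
    X: np.ndarray, k: int, fit_fn: Callable[[np.ndarray, int], FitResult]
) -> tuple[FitResult | None, float]:
    try:
        fit = fit_fn(X, k)
    except (ValueError, FloatingPointError) as exc:
        warnings.warn(f"fit at K={k} failed ({exc}); candidate skipped")
        return None, np.nan
    return fit, bic_score(fit.loglik, k, X.shape[1], X.shape[0])


def select_k(
    X: np.ndarray,
    *,
    k_min: int = 1,
    k_step: int = 1,
    k_max: int | None = None,
    fit_fn: Callable[[np.ndarray, int], FitResult],
) -> SelectionTrace:
    """Linear BIC scan: K = k_min, k_min+k_step, ... until the BIC increases.

    ``fit_fn(X, k)`` must return a :class:`FitResult`; a candidate whose fit
    raises is recorded as skipped (with a warning) and the scan continues.
    ``chosen_K`` minimizes BIC among the successfully evaluated candidates.
    If the BIC is still decreasing at ``k_max`` the trace carries
    ``cap_reached=True``.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    n = X.shape[0]
    cap = min(k_max, n) if k_max is not None else n
    trace = SelectionTrace()
    prev_bic = np.inf
    k = k_min
    while k <= cap:
        fit, bic = _evaluate(X, k, fit_fn)
        if fit is not None:
            trace.candidate_Ks.append(k)
            trace.bic_scores.append(bic)
            trace.fits.append(fit)
            if bic > prev_bic:
                break
            prev_bic = bic
        k += k_step
    else:
        if trace.candidate_Ks and trace.bic_scores[-1] <= prev_bic:
            trace.cap_reached = True
    if not trace.candidate_Ks:
        raise RuntimeError("no candidate K could be fitted")
    trace.chosen_K = trace.candidate_Ks[int(np.argmin(trace.bic_scores))]
    return trace


def select_k_geometric(
    X: np.ndarray,
    *,
    k_min: int = 1,
    k_max: int | None = None,
    refine_step: int = 1,
    fit_fn: Callable[[np.ndarray, int], FitResult],
) -> SelectionTrace:
    """Doubling pre-scan followed by a linear refinement.

    Doubles K from ``k_min`` until the BIC increases (bracketing the
    minimum), then runs :func:`select_k` with ``refine_step`` inside the
    bracket.  The stopping rule on the refined scan is unchanged: first BIC
    increase.
    """
    n = X.shape[0]
    cap = min(k_max, n) if k_max is not None else n
    ks: list[int] = []
    bics: list[float] = []
    k = k_min
    while k <= cap:
        fit, bic = _evaluate(X, k, fit_fn)
        if fit is not None:
            ks.append(k)
            bics.append(bic)
            if len(bics) > 1 and bics[-1] > bics[-2]:
                break
        k *= 2
    if not ks:
        raise RuntimeError("no candidate K could be fitted")
    best = int(np.argmin(bics))
    lo = ks[best - 1] if best > 0 else ks[best]
    hi = ks[best + 1] if best + 1 < len(ks) else min(ks[best] * 2, cap)
    return select_k(X, k_min=lo, k_step=refine_step, k_max=hi, fit_fn=fit_fn)
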