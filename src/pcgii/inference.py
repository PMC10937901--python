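"""FDR-controlled edge discovery from partial-correlation statistics.

Under the null hypothesis rho[j1,j2] = 0 the statistic
``T[j1,j2] = sqrt(n) * rho_hat[j1,j2]`` is asymptotically standard normal,
so with a threshold level ``tau`` the candidate edge set is

    D(tau) = {(j1,j2) : |T[j1,j2]| > tau * sqrt(log p)}

and the expected number of false positives is approximately
``B(tau) * m0`` with ``B(tau) = 2 - 2*Phi(tau*sqrt(log p))`` and the number
of true nulls ``m0`` bounded by ``p^2 - p`` (ordered off-diagonal pairs).
Storey-style plug-in FDR control selects

    tau_hat = inf{ tau in (0, 2] : B(tau)*(p^2 - p) / max(1, |D(tau)|) <= alpha }

where ``|D(tau)|`` counts ordered pairs (twice the unordered count) so
numerator and denominator are on the same scale.  When no ``tau``
satisfies the bound, the most conservative value ``tau_hat = 2`` is used
and flagged.

The infimum is computed exactly: on each interval between consecutive
observed values of ``|T|/sqrt(log p)`` the discovery set is constant while
``B`` decreases continuously, so the crossing point inside the first
feasible interval is available in closed form via the normal quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.utils.validation import check_is_fitted

from .nodewise import PartialCorrelationEstimator, estimate_partial_correlations

__all__ = [
    "null_tail_probability",
    "candidate_set",
    "select_threshold",
    "infer_network",
    "InferenceResult",
    "PCGII",
]


def null_tail_probability(tau: float, p: int) -> float:
    """Two-sided standard-normal tail beyond ``tau * sqrt(log p)``."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if p < 2:
        raise ValueError("p must be at least 2")
    return float(2.0 * norm.sf(tau * math.sqrt(math.log(p))))


def _offdiag_abs(statistics: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    stats = np.asarray(statistics, dtype=float)
    iu = np.triu_indices(stats.shape[0], k=1)
    return np.abs(stats[iu]), iu[0], iu[1]


def candidate_set(statistics: np.ndarray, tau: float, p: int) -> frozenset:
    """Unordered pairs with ``|T| > tau * sqrt(log p)`` (strict)."""
    absT, ii, jj = _offdiag_abs(statistics)
    cut = tau * math.sqrt(math.log(p))
    keep = absT > cut
    return frozenset(zip(ii[keep].tolist(), jj[keep].tolist()))


def select_threshold(
    statistics: np.ndarray, alpha: float, p: int
) -> tuple[float, bool]:
    """Exact infimum of the FDR-control criterion over ``tau in (0, 2]``.

    Returns ``(tau_hat, fallback_used)``; ``fallback_used`` is True when no
    tau satisfies the criterion and the conservative ``tau_hat = 2`` is
    returned.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    absT, _, _ = _offdiag_abs(statistics)
    sqrt_log_p = math.sqrt(math.log(p))
    m0 = p * p - p
    t = np.sort(absT / sqrt_log_p)  # candidate change points, ascending

    # intervals [left, right) of constant D; left endpoints: 0 and each
    # distinct candidate < 2; the final interval is closed at tau = 2.
    lefts = np.concatenate([[0.0], np.unique(t[(t > 0) & (t < 2.0)])])
    for i, left in enumerate(lefts):
        right = lefts[i + 1] if i + 1 < len(lefts) else 2.0
        d_size = 2 * int(np.count_nonzero(t > left))  # ordered-pair count
        denom = max(1, d_size)
        # smallest attainable criterion value on this interval (at tau -> right)
        b_right = 2.0 * norm.sf(right * sqrt_log_p)
        if b_right * m0 / denom <= alpha:
            # crossing: B(tau*) = alpha * denom / m0
            tail = alpha * denom / (2.0 * m0)
            tau_star = norm.isf(tail) / sqrt_log_p
            return float(min(max(tau_star, left), right)), False
    return 2.0, True


@dataclass
class InferenceResult:
    """Discovered edge set with the statistics and threshold behind it."""

    statistics: np.ndarray
    tau_hat: float
    alpha: float
    discoveries: frozenset
    fallback_used: bool
    rho_hat: np.ndarray | None = None
    n: int | None = None

    @property
    def p(self) -> int:
        return self.statistics.shape[0]


class PCGII(PartialCorrelationEstimator):
    """Partial-correlation graph with information incorporation.

    Fits the de-biased node-wise partial-correlation estimator (optionally
    exempting prior-known edges from the penalty) and applies the
    tau-threshold multiple-testing procedure to recover the network at a
    nominal FDR level.

    Parameters
    ----------
    alpha : nominal FDR level in (0, 1).
    (remaining parameters as in :class:`PartialCorrelationEstimator`)

    Attributes (after ``fit``)
    --------------------------
    statistics_ : ``sqrt(n) * rho_``.
    tau_ : selected threshold parameter in (0, 2].
    fallback_ : True when no threshold satisfied the criterion.
    discoveries_ : frozenset of unordered index pairs.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        prior=None,
        lam="auto",
        standardize: bool = True,
        tol: float = 1e-8,
        max_iter: int = 10000,
    ):
        super().__init__(
            prior=prior, lam=lam, standardize=standardize, tol=tol, max_iter=max_iter
        )
        self.alpha = alpha

    def fit(self, X, y=None):
        super().fit(X)
        p = self.n_features_in_
        self.tau_, self.fallback_ = select_threshold(self.statistics_, self.alpha, p)
        self.discoveries_ = candidate_set(self.statistics_, self.tau_, p)
        return self

    @property
    def result_(self) -> InferenceResult:
        check_is_fitted(self, "discoveries_")
        return InferenceResult(
            statistics=self.statistics_,
            tau_hat=self.tau_,
            alpha=self.alpha,
            discoveries=self.discoveries_,
            fallback_used=self.fallback_,
            rho_hat=self.rho_,
            n=self.n_samples_,
        )


def infer_network(
    Y: np.ndarray,
    prior=None,
    alpha: float = 0.05,
    lam=None,
    tol: float = 1e-8,
    max_iter: int = 10000,
    standardize: bool = True,
) -> InferenceResult:
    """Estimate partial correlations and discover edges with FDR control.

    Deterministic given ``(Y, prior, lam, alpha)``.
    """
    est = estimate_partial_correlations(
        Y, prior=prior, lam=lam, tol=tol, max_iter=max_iter, standardize=standardize
    )
    p = est.p
    T = est.statistics
    tau_hat, fallback = select_threshold(T, alpha, p)
    return InferenceResult(
        statistics=T,
        tau_hat=tau_hat,
        alpha=alpha,
        discoveries=candidate_set(T, tau_hat, p),
        fallback_used=fallback,
        rho_hat=est.rho_hat,
        n=est.n,
    )
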