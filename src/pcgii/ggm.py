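"""Population-level Gaussian graphical model math.

A Gaussian graphical model on ``p`` genes is parameterized by a symmetric
positive-definite precision matrix ``Omega = Sigma^{-1}``.  Two genes are
conditionally independent given all others exactly when the corresponding
off-diagonal precision entry is zero, and the strength of a conditional
association is measured by the partial correlation

    rho[j1, j2] = -omega[j1, j2] / sqrt(omega[j1, j1] * omega[j2, j2]).

Equivalently, writing each variable as a linear regression on all the
others, the covariance matrix ``V`` of the p regression errors satisfies
``v[j1, j2] = omega[j1, j2] / (omega[j1, j1] * omega[j2, j2])`` and
``rho[j1, j2] = -v[j1, j2] / sqrt(v[j1, j1] * v[j2, j2])``.

Everything here is population-level (no estimation); it provides ground
truth for the simulator and exact oracles for estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PrecisionModel",
    "validate_spd",
    "partial_correlation_from_precision",
    "population_residual_covariance",
    "precision_model_from_omega",
]

#: default eigenvalue floor for positive-definiteness checks; simulated
#: precision matrices are near-diagonally-dominant so a loose floor suffices
SPD_TOL = 1e-10


def validate_spd(omega: np.ndarray, tol: float = SPD_TOL) -> np.ndarray:
    """Validate that ``omega`` is a symmetric positive-definite matrix.

    Returns the validated array (as float ndarray).  Raises ``ValueError``
    naming the smallest eigenvalue when the matrix is not SPD.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {omega.shape}")
    if not np.allclose(omega, omega.T, atol=1e-8, rtol=1e-8):
        raise ValueError("matrix is not symmetric")
    smallest = float(np.linalg.eigvalsh(omega)[0])
    if smallest <= tol:
        raise ValueError(
            f"matrix is not positive definite: smallest eigenvalue {smallest:.6g} "
            f"<= tolerance {tol:.6g}"
        )
    return omega


def partial_correlation_from_precision(
    omega: np.ndarray, tol: float = SPD_TOL
) -> np.ndarray:
    """Partial-correlation matrix of an SPD precision matrix.

    ``rho[j1, j2] = -omega[j1, j2] / sqrt(omega[j1, j1] * omega[j2, j2])``
    with the diagonal set to 1.
    """
    omega = validate_spd(omega, tol=tol)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def population_residual_covariance(
    omega: np.ndarray, tol: float = SPD_TOL
) -> np.ndarray:
    """Error covariance ``V`` of the p population node-wise regressions.

    ``v[j1, j2] = omega[j1, j2] / (omega[j1, j1] * omega[j2, j2])`` for
    ``j1 != j2`` and ``v[j, j] = 1 / omega[j, j]``.
    """
    omega = validate_spd(omega, tol=tol)
    d = np.diag(omega)
    v = omega / np.outer(d, d)
    np.fill_diagonal(v, 1.0 / d)
    return v


@dataclass
class PrecisionModel:
    """A Gaussian graphical model: precision, covariance, support, truth.

    Attributes
    ----------
    omega : (p, p) SPD precision matrix.
    sigma : (p, p) covariance matrix, ``inv(omega)``.
    support : frozenset of unordered index pairs ``(j1, j2)``, ``j1 < j2``,
        with ``omega[j1, j2] != 0`` — the true edge set.
    rho : (p, p) true partial-correlation matrix.
    mu : optional length-p mean vector (zeros if omitted); used by the
        simulator for count data.
    """

    omega: np.ndarray
    sigma: np.ndarray
    support: frozenset
    rho: np.ndarray
    mu: np.ndarray | None = field(default=None)

    @property
    def p(self) -> int:
        return self.omega.shape[0]

    @property
    def m1(self) -> int:
        """Number of true edges (unordered pairs)."""
        return len(self.support)

    def validate(self, tol: float = SPD_TOL) -> "PrecisionModel":
        """Check internal consistency; raise ``ValueError`` on violation."""
        validate_spd(self.omega, tol=tol)
        p = self.p
        if self.sigma.shape != (p, p):
            raise ValueError("sigma shape mismatch")
        if not np.allclose(self.sigma @ self.omega, np.eye(p), atol=1e-6):
            raise ValueError("sigma is not the inverse of omega")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho diagonal must be 1")
        off = self.rho[~np.eye(p, dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("off-diagonal partial correlations must lie in (-1, 1)")
        expected = support_from_omega(self.omega)
        if expected != self.support:
            raise ValueError("support does not match nonzeros of omega")
        return self


def support_from_omega(omega: np.ndarray, zero_tol: float = 1e-12) -> frozenset:
    """Unordered index pairs with off-diagonal ``|omega| > zero_tol``."""
    p = omega.shape[0]
    iu = np.triu_indices(p, k=1)
    nz = np.abs(omega[iu]) > zero_tol
    return frozenset(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))


def precision_model_from_omega(
    omega: np.ndarray, mu: np.ndarray | None = None, tol: float = SPD_TOL
) -> PrecisionModel:
    """Build a :class:`PrecisionModel` from a precision matrix alone."""
    omega = validate_spd(omega, tol=tol)
    sigma = np.linalg.inv(omega)
    sigma = (sigma + sigma.T) / 2.0
    return PrecisionModel(
        omega=omega,
        sigma=sigma,
        support=support_from_omega(omega),
        rho=partial_correlation_from_precision(omega, tol=tol),
        mu=None if mu is None else np.asarray(mu, dtype=float),
    )
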