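"""Harmonic Gaussian basis and the decomposition-based penalty operator.

Walking energy concentrates at integer and half-integer multiples of the
cadence.  The informative subspace Q is spanned by Gaussian bells centered
at order multiples 0.5, 1.0, ..., 5.5 with a common standard deviation small
enough that the columns are nearly orthogonal.  The penalty operator

    L = a (I - P_Q) + P_Q,        P_Q = Q Q^+,  a > 0,

leaves the informative subspace penalized as ordinary ridge (eigenvalue 1 of
L^T L) while shrinking its orthogonal complement a^2-fold harder.  a = 1
recovers plain ridge regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateBasisError, ParameterError

__all__ = ["HarmonicBasis", "PenaltyOperator", "build_basis", "projection", "penalty_operator"]

_PINV_RCOND = 1e-10  # singular values below rcond * s_max count as zero


@dataclass
class HarmonicBasis:
    """Gaussian bells at cadence multiples, evaluated on the order grid."""

    order_grid: np.ndarray
    centers: np.ndarray
    sd: float
    Q: np.ndarray  # p x m, columns unit-norm

    @property
    def n_basis(self) -> int:
        return self.Q.shape[1]

    def max_offdiag_inner(self) -> float:
        """Largest off-diagonal normalized inner product between columns."""
        G = self.Q.T @ self.Q
        norms = np.sqrt(np.diag(G))
        C = G / np.outer(norms, norms)
        np.fill_diagonal(C, 0.0)
        return float(np.abs(C).max())


@dataclass
class PenaltyOperator:
    """L = a (I - P_Q) + P_Q with its building blocks."""

    a: float
    P_Q: np.ndarray
    L: np.ndarray

    @property
    def LtL(self) -> np.ndarray:
        return self.L.T @ self.L

    @property
    def L_inv(self) -> np.ndarray:
        """Closed-form inverse (1/a)(I - P_Q) + P_Q; exists for any a > 0."""
        p = self.P_Q.shape[0]
        return (np.eye(p) - self.P_Q) / self.a + self.P_Q


def build_basis(
    grid: np.ndarray,
    sd: float = 0.08,
    center_step: float = 0.5,
    center_min: float = 0.5,
    center_max: float = 5.5,
    normalize: bool = True,
) -> HarmonicBasis:
    """Gaussian-density columns centered at multiples of the cadence.

    With the defaults the centers are 0.5, 1.0, ..., 5.5 (11 columns).
    Columns are scaled to unit Euclidean norm; the projection P_Q is
    invariant to column scaling, so this only conditions the pseudo-inverse.
    """
    if sd <= 0:
        raise ParameterError("basis sd must be positive")
    if center_step <= 0 or center_max < center_min:
        raise ParameterError("invalid center range")
    grid = np.asarray(grid, dtype=float)
    n_centers = int(round((center_max - center_min) / center_step)) + 1
    centers = center_min + center_step * np.arange(n_centers)
    Q = stats.norm.pdf(grid[:, None], loc=centers[None, :], scale=sd)
    if normalize:
        norms = np.linalg.norm(Q, axis=0)
        if np.any(norms == 0):
            raise DegenerateBasisError("a basis column vanishes on the grid")
        Q = Q / norms
    return HarmonicBasis(order_grid=grid, centers=centers, sd=float(sd), Q=Q)


def projection(Q: np.ndarray) -> np.ndarray:
    """Orthogonal projection P_Q = Q Q^+ onto the column span of Q."""
    Q = np.asarray(Q, dtype=float)
    s = np.linalg.svd(Q, compute_uv=False)
    if s[-1] <= _PINV_RCOND * s[0]:
        raise DegenerateBasisError(
            f"basis is numerically rank deficient (cond {s[0] / s[-1]:.2e})"
        )
    P = Q @ np.linalg.pinv(Q, rcond=_PINV_RCOND)
    return (P + P.T) / 2.0  # enforce exact symmetry


def penalty_operator(P_Q: np.ndarray, a: float = 2.0) -> PenaltyOperator:
    """Decomposition penalty L = a (I - P_Q) + P_Q.

    Directions orthogonal to span(Q) enter ||L beta||^2 with weight a^2;
    directions within span(Q) with weight 1.
    """
    if a <= 0:
        raise ParameterError("penalty weight a must be positive")
    P_Q = np.asarray(P_Q, dtype=float)
    p = P_Q.shape[0]
    L = a * (np.eye(p) - P_Q) + P_Q
    return PenaltyOperator(a=float(a), P_Q=P_Q, L=L)
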