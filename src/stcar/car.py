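"""Leroux-type conditional autoregressive (CAR) Gaussian fields.

A CAR field u on a lattice with adjacency W and degree matrix D_w has
precision (at unit variance scale)

    Q(rho) = rho * (D_w - W) + (1 - rho) * I,      0 <= rho < 1,

interpolating between independence (rho = 0, Q = I) and the intrinsic CAR
(rho = 1, Q singular on connected graphs).  The field's covariance is
tau2 * Q(rho)^{-1}.  For rho < 1 the prior is proper, so the log-density
has a well-defined normalising constant and exact sampling reduces to one
Cholesky factorisation.  Problem sizes here are at most a few dozen nodes,
so all linear algebra is dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .lattice import SpatialLattice

__all__ = [
    "CarStructure",
    "leroux_precision",
    "car_logdensity",
    "car_logdensity_multi",
    "sample_car_field",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class CarStructure:
    """A Leroux CAR field: lattice + dependence rho + variance tau2."""

    lattice: SpatialLattice
    rho: float
    tau2: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.tau2 <= 0.0:
            raise ValueError(f"tau2 must be > 0, got {self.tau2}")

    def precision(self) -> np.ndarray:
        """Full precision Q(rho) / tau2."""
        return leroux_precision(self.lattice, self.rho) / self.tau2


def leroux_precision(lattice: SpatialLattice, rho: float) -> np.ndarray:
    """Unit-variance Leroux precision Q(rho) = rho (D_w - W) + (1 - rho) I.

    rho = 1 (intrinsic CAR limit) is permitted for structure inspection only;
    density evaluation and sampling require rho < 1.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    W = lattice.adjacency()
    deg = lattice.neighbour_counts.astype(float)
    Q = -rho * W
    np.fill_diagonal(Q, rho * deg + (1.0 - rho))
    return Q


def _chol_precision(structure: CarStructure) -> np.ndarray:
    """Upper Cholesky factor of Q(rho)/tau2; raises on numerical non-PD."""
    P = structure.precision()
    try:
        return cholesky(P, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"CAR precision not positive-definite (rho={structure.rho})"
        ) from exc


def car_logdensity(u: np.ndarray, structure: CarStructure) -> float:
    """Proper multivariate-normal log-density of a CAR field at u.

    Mean zero, precision Q(rho)/tau2, including the 1/2 log-determinant
    normalising term.
    """
    return car_logdensity_multi(np.atleast_2d(u), structure)


def car_logdensity_multi(U: np.ndarray, structure: CarStructure) -> float:
    """Joint log-density of k independent CAR fields sharing one structure.

    ``U`` has shape (k, n): k replicate fields on the same lattice with the
    same (rho, tau2).  Used for the autoregressive family, whose innovation
    slices are iid CAR fields.  The Cholesky factor is computed once.
    """
    U = np.atleast_2d(np.asarray(U, float))
    k, n = U.shape
    if n != structure.lattice.n_areas:
        raise ValueError(
            f"field length {n} != lattice size {structure.lattice.n_areas}"
        )
    R = _chol_precision(structure)  # Q/tau2 = R' R
    logdet_half = float(np.sum(np.log(np.diag(R))))  # 1/2 log det(Q/tau2)
    quad = float(np.sum((U @ R.T) ** 2))  # sum_i u_i' (Q/tau2) u_i
    return k * (-0.5 * n * _LOG_2PI + logdet_half) - 0.5 * quad


def sample_car_field(
    structure: CarStructure, rng: np.random.Generator | int
) -> np.ndarray:
    """Exact draw u ~ N(0, tau2 * Q(rho)^{-1}) via the precision Cholesky.

    With Q/tau2 = R'R (R upper triangular), u = R^{-1} z for z ~ N(0, I)
    has the required covariance.  Deterministic given the Generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    R = _chol_precision(structure)
    z = rng.standard_normal(structure.lattice.n_areas)
    return solve_triangular(R, z, lower=False)


def car_conditional_cov(structure: CarStructure) -> np.ndarray:
    """Dense covariance tau2 * Q(rho)^{-1} (small lattices only)."""
    R = _chol_precision(structure)
    n = structure.lattice.n_areas
    return cho_solve((R, False), np.eye(n))
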