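"""Growth model for sexually reproducing populations with heritable dispersal ability.

The population is partitioned into ``n`` genotypes.  Genotype ``k`` moves as a
random walk with step-size parameter (dispersal ability) ``a_k = a0 * k`` and
therefore diffuses with coefficient ``a_k**2 / 4``.  Births arise from random
pairwise encounters between individuals, so the local rate of matings between
genotypes ``i`` and ``j`` is proportional to the product of their densities
(a bimolecular-collision mate-finding term), attenuated by a logistic crowding
factor as the habitat approaches its carrying capacity.  An inheritance kernel
``chi[k, i, j]`` gives the probability that an (i, j) mating produces a
genotype-``k`` offspring; with the Mendelian 50/50 kernel every genotype shares
the same per-capita growth rate

    c(psi) = beta * psi * (1 - psi) - delta        (densities in units of K)

which is negative at low density -- a strong, mate-finding Allee effect -- and
bistable between extinction (psi -> 0) and saturation (psi -> psi_plus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "InheritanceKernel",
    "FixedPoints",
    "make_mendelian_kernel",
    "per_capita_growth",
    "fixed_points",
    "birth_term_general",
    "birth_term_mendelian",
    "nondimensionalize",
]


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional model parameters.

    Parameters
    ----------
    n
        Number of dispersal-ability genotypes (bins); genotype ``k`` has
        dispersal ability ``a0 * k`` for ``k = 1, ..., n``.
    beta
        Rescaled birth parameter (collision rate times carrying capacity).
    delta
        Rescaled per-capita death rate.  May be superseded by a spatially
        varying death field at simulation time.
    a0
        Dispersal-ability unit; 1 in nondimensional runs, so the diffusion
        coefficient of genotype ``k`` is ``k**2 / 4``.
    """

    n: int = 5
    beta: float = 380.0
    delta: float = 36.0
    a0: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if self.beta < 0 or self.delta < 0:
            raise ValueError("beta and delta must be non-negative")
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")

    @property
    def dispersal_abilities(self) -> np.ndarray:
        """Per-genotype dispersal abilities ``a_k = a0 * k``."""
        return self.a0 * np.arange(1, self.n + 1, dtype=float)

    @property
    def diffusivities(self) -> np.ndarray:
        """Per-genotype diffusion coefficients ``a_k**2 / 4``."""
        return self.dispersal_abilities**2 / 4.0


class InheritanceKernel:
    """Rank-3 tensor ``chi[k, i, j]``: probability that parents of genotypes
    ``i`` and ``j`` (0-based indices here) produce a genotype-``k`` offspring.

    Entries lie in [0, 1] and sum to 1 over ``k`` for every parent pair.
    """

    def __init__(self, chi: np.ndarray):
        chi = np.asarray(chi, dtype=float)
        if chi.ndim != 3 or len(set(chi.shape)) != 1:
            raise ValueError(f"kernel must have shape (n, n, n), got {chi.shape}")
        if np.any(chi < -1e-12) or np.any(chi > 1 + 1e-12):
            raise ValueError("kernel entries must lie in [0, 1]")
        col = chi.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-12):
            raise ValueError("kernel columns must sum to 1 over offspring genotype")
        self.chi = chi

    @property
    def n(self) -> int:
        return self.chi.shape[0]


def make_mendelian_kernel(n: int) -> InheritanceKernel:
    """Kernel in which offspring inherit either parent's genotype with
    probability 1/2 each: ``chi[k, i, j] = (1[i == k] + 1[j == k]) / 2``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    eye = np.eye(n)
    chi = 0.5 * (eye[:, :, None] + eye[:, None, :])
    return InheritanceKernel(chi)


def per_capita_growth(psi, beta: float, delta: float):
    """Net per-capita growth rate ``c(psi) = beta*psi*(1 - psi) - delta``.

    ``psi`` is the overall density as a fraction of carrying capacity and must
    be non-negative; the rate is shared by all genotypes.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0):
        raise ValueError("psi must be non-negative")
    out = beta * psi * (1.0 - psi) - delta
    return out if out.ndim else float(out)


class FixedPoints(NamedTuple):
    """Interior fixed points of the well-mixed dynamics.

    ``psi_minus`` is the Allee threshold, ``psi_plus`` the saturation density.
    When ``4*delta > beta`` there is no positive-growth window: ``persistent``
    is False and both roots are NaN (extinction is the only attractor).
    """

    psi_minus: float
    psi_plus: float
    persistent: bool


def fixed_points(beta: float, delta: float) -> FixedPoints:
    """Roots of ``beta*psi*(1 - psi) = delta``:
    ``psi_-+ = (1 -+ sqrt(1 - 4*delta/beta)) / 2``.
    """
    if beta <= 0:
        return FixedPoints(np.nan, np.nan, False)
    disc = 1.0 - 4.0 * delta / beta
    if disc < 0:
        return FixedPoints(np.nan, np.nan, False)
    root = np.sqrt(disc)
    return FixedPoints(0.5 * (1.0 - root), 0.5 * (1.0 + root), True)


def birth_term_general(fields: np.ndarray, kernel: InheritanceKernel, beta: float) -> np.ndarray:
    """Per-genotype birth rate for an arbitrary inheritance kernel:

    ``beta * sum_ij chi[k,i,j] * Psi_i * Psi_j * (1 - Psi)``

    Summed over offspring genotype ``k`` this equals ``beta*Psi**2*(1 - Psi)``
    (every mating produces exactly one offspring distribution).
    """
    fields = np.asarray(fields, dtype=float)
    if fields.shape[0] != kernel.n:
        raise ValueError(
            f"field stack has {fields.shape[0]} genotypes, kernel expects {kernel.n}"
        )
    if np.any(fields < 0):
        raise ValueError("fields must be non-negative")
    total = fields.sum(axis=0)
    pairings = np.einsum("kij,i...,j...->k...", kernel.chi, fields, fields)
    return beta * pairings * (1.0 - total)


def birth_term_mendelian(fields: np.ndarray, beta: float) -> np.ndarray:
    """Fast path for the Mendelian kernel: ``beta*Psi*(1 - Psi)*Psi_k``.

    Equivalent to :func:`birth_term_general` with
    :func:`make_mendelian_kernel`; kept separate because it avoids the
    O(n^3) pairing sum and is the form actually integrated.
    """
    fields = np.asarray(fields, dtype=float)
    total = fields.sum(axis=0)
    return beta * total * (1.0 - total) * fields


def nondimensionalize(K: float, r0: float, a0: float, b: float, d: float) -> tuple[float, float]:
    """Map dimensional parameters to the two nondimensional groups.

    With densities in units of the carrying capacity ``K``, lengths in units
    of ``r0`` and time rescaled by ``(a0/r0)**2``, the dynamics depend only on

        beta = K * (r0/a0)**2 * b,    delta = (r0/a0)**2 * d.
    """
    for name, val in (("K", K), ("r0", r0), ("a0", a0), ("b", b), ("d", d)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    scale = (r0 / a0) ** 2
    return K * scale * b, scale * d
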