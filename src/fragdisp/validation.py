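"""Independent oracles used to validate the simulator.

* a high-accuracy 0-D (well-mixed) ODE integration of the shared-growth-rate
  dynamics, against which spatially uniform PDE runs must agree;
* the classical critical-patch-size check: the square root of the smallest
  Dirichlet eigenvalue of the Laplacian on the unit disk equals the first
  zero of the Bessel function J0, approximately 2.405, which validates the
  finite-difference diffusion operator against a closed form;
* a bistability classifier for uniform initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import eigsh

from .model import fixed_points

__all__ = [
    "OracleResult",
    "DiskEigenResult",
    "BESSEL_J0_FIRST_ZERO",
    "wellmixed_oracle",
    "disk_dirichlet_eigen",
    "classify_bistable",
]

#: First positive zero of the order-zero Bessel function J0.
BESSEL_J0_FIRST_ZERO = 2.404825557695773


@dataclass(frozen=True)
class OracleResult:
    quantity: str
    computed: float
    reference: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.reference) <= self.tolerance


def wellmixed_oracle(
    beta: float,
    delta: float,
    psi0,
    t_grid,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Integrate the well-mixed dynamics
    ``dPsi_k/dt = (beta*Psi*(1 - Psi) - delta) * Psi_k`` to high accuracy.

    Because the per-capita rate is shared, genotype frequencies are conserved
    along trajectories.  Returns the (len(t_grid), n) trajectory.
    """
    psi0 = np.atleast_1d(np.asarray(psi0, dtype=float))
    if np.any(psi0 < 0):
        raise ValueError("initial densities must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)

    def f(t, y):
        tot = y.sum()
        return (beta * tot * (1.0 - tot) - delta) * y

    sol = solve_ivp(
        f,
        (t_grid[0], t_grid[-1]),
        psi0,
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    return sol.y.T


def _disk_laplacian(dx: float, radius: float, stencil: int) -> tuple[sp.csr_matrix, int]:
    """Sparse negative Laplacian on grid nodes strictly inside the disk, with
    zero (absorbing) values at all exterior nodes."""
    m = int(np.floor(radius / dx)) + 1
    coords = np.arange(-m, m + 1) * dx
    X, Y = np.meshgrid(coords, coords)
    inside = X**2 + Y**2 < radius**2
    idx = -np.ones(inside.shape, dtype=int)
    idx[inside] = np.arange(int(inside.sum()))
    nn = int(inside.sum())

    rows, cols, vals = [], [], []
    if stencil == 5:
        offsets = [(0, 1, 1.0), (0, -1, 1.0), (1, 0, 1.0), (-1, 0, 1.0)]
        center = 4.0
        scale = 1.0 / dx**2
    elif stencil == 9:
        offsets = [
            (0, 1, 4.0), (0, -1, 4.0), (1, 0, 4.0), (-1, 0, 4.0),
            (1, 1, 1.0), (1, -1, 1.0), (-1, 1, 1.0), (-1, -1, 1.0),
        ]
        center = 20.0
        scale = 1.0 / (6.0 * dx**2)
    else:
        raise ValueError("stencil must be 5 or 9")

    jj, ii = np.nonzero(inside)
    for dj, di, w in offsets:
        j2, i2 = jj + dj, ii + di
        ok = (j2 >= 0) & (j2 < idx.shape[0]) & (i2 >= 0) & (i2 < idx.shape[1])
        ok[ok] &= idx[j2[ok], i2[ok]] >= 0
        rows.extend(idx[jj[ok], ii[ok]])
        cols.extend(idx[j2[ok], i2[ok]])
        vals.extend(np.full(int(ok.sum()), -w * scale))
    rows.extend(idx[jj, ii])
    cols.extend(idx[jj, ii])
    vals.extend(np.full(nn, center * scale))
    A = sp.csr_matrix((vals, (rows, cols)), shape=(nn, nn))
    return A, nn


@dataclass(frozen=True)
class DiskEigenResult:
    dx: tuple[float, ...]
    lambda1: tuple[float, ...]
    n_nodes: tuple[int, ...]
    sqrt_lambda1: float  # Richardson-extrapolated
    order: float  # convergence order used in the extrapolation

    @property
    def sqrt_lambda1_finest(self) -> float:
        return float(np.sqrt(self.lambda1[-1]))


def disk_dirichlet_eigen(
    dx_list, radius: float = 1.0, stencil: int = 5
) -> DiskEigenResult:
    """Smallest eigenvalue of the Dirichlet (absorbing-boundary) Laplacian on
    a disk, by finite differences on an embedded grid, with Richardson
    extrapolation across the refinement levels.

    For the unit disk ``sqrt(lambda_1)`` converges to the first zero of J0
    (about 2.405), the constant in the classical uniform decay rate
    ``c - a**2 j1**2 / (4 r0**2)`` for a diffusing population on an absorbing
    disk.  Because the disk boundary cuts between grid nodes, the dominant
    eigenvalue error is first order in ``dx``; the extrapolation assumes that
    order unless three or more levels are supplied, in which case the order
    is estimated from the data.
    """
    dx_list = sorted(float(d) for d in np.atleast_1d(dx_list))[::-1]
    if len(dx_list) < 2:
        raise ValueError("need at least two refinement levels")
    lams, nns = [], []
    for dx in dx_list:
        A, nn = _disk_laplacian(dx, radius, stencil)
        if nn < 100:
            raise ValueError(f"grid too coarse at dx={dx}: only {nn} interior nodes")
        lam = eigsh(A, k=1, sigma=0, which="LM", return_eigenvectors=False)[0]
        lams.append(float(lam))
        nns.append(nn)

    if len(dx_list) >= 3:
        r = dx_list[-3] / dx_list[-2]
        order = float(
            np.log(abs((lams[-3] - lams[-2]) / (lams[-2] - lams[-1]))) / np.log(r)
        )
    else:
        order = 1.0
    r = dx_list[-2] / dx_list[-1]
    lam_ext = lams[-1] + (lams[-1] - lams[-2]) / (r**order - 1.0)
    return DiskEigenResult(
        dx=tuple(dx_list),
        lambda1=tuple(lams),
        n_nodes=tuple(nns),
        sqrt_lambda1=float(np.sqrt(lam_ext)),
        order=order,
    )


def classify_bistable(
    beta: float,
    delta: float,
    psi0_grid,
    n: int = 1,
    t_chunk: float = 2.0,
    max_chunks: int = 50,
    tol: float = 1e-8,
) -> list[str]:
    """Classify the fate of uniform initial conditions under the well-mixed
    dynamics: ``"extinct"`` (decay to 0), ``"saturation"`` (convergence to the
    upper fixed point) or ``"threshold"`` for an initial density that sits on
    the Allee threshold to within ``tol``.
    """
    fp = fixed_points(beta, delta)
    if not fp.persistent:
        raise ValueError("no interior fixed points: 4*delta > beta")
    outcomes = []
    for psi0 in np.atleast_1d(psi0_grid):
        psi0 = float(psi0)
        if abs(psi0 - fp.psi_minus) <= tol:
            outcomes.append("threshold")
            continue
        y = np.full(n, psi0 / n)
        verdict = "undetermined"
        for _ in range(max_chunks):
            traj = wellmixed_oracle(beta, delta, y, [0.0, t_chunk])
            y = traj[-1]
            tot = y.sum()
            if tot < 1e-10:
                verdict = "extinct"
                break
            if abs(tot - fp.psi_plus) < tol:
                verdict = "saturation"
                break
        outcomes.append(verdict)
    return outcomes
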