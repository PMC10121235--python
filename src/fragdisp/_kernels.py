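"""Compiled inner loops for the right-hand side evaluation.

The adaptive integrator calls the right-hand side hundreds of thousands of
times per run, so the fused 9-point-Laplacian + reaction update is JIT
compiled.  The pure-numpy implementation in :mod:`fragdisp.numerics` is the
readable reference; the two are asserted equal in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rhs_kernel(psi, dcoef, beta, delta_map, dx, out):  # pragma: no cover - exercised via numerics
    n, ny, nx = psi.shape
    c = 1.0 / (6.0 * dx * dx)
    growth = np.empty((ny, nx))
    for j in range(ny):
        for i in range(nx):
            tot = 0.0
            for k in range(n):
                tot += psi[k, j, i]
            growth[j, i] = beta * tot * (1.0 - tot) - delta_map[j, i]
    for k in range(n):
        D = dcoef[k]
        for j in range(ny):
            jm = j - 1 if j > 0 else ny - 1
            jp = j + 1 if j < ny - 1 else 0
            for i in range(nx):
                im = i - 1 if i > 0 else nx - 1
                ip = i + 1 if i < nx - 1 else 0
                lap = c * (
                    4.0 * (psi[k, jm, i] + psi[k, jp, i] + psi[k, j, im] + psi[k, j, ip])
                    + psi[k, jm, im]
                    + psi[k, jm, ip]
                    + psi[k, jp, im]
                    + psi[k, jp, ip]
                    - 20.0 * psi[k, j, i]
                )
                out[k, j, i] = D * lap + growth[j, i] * psi[k, j, i]
    return out
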