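"""Periodic computational grids and fragmented initial-population layouts.

The simulated rectangle is a periodic tile of an infinite equilateral
triangular lattice of circular population fragments with nearest-neighbour
spacing ``s``.  One fragment sits at the tile centre and the second lattice
point of the rectangular unit cell appears as quarter-discs in the four
corners, so each ``s x sqrt(3)*s`` tile carries exactly two whole fragments.
A two-scale variant groups "micro"-discs into hexagonal "macro"-fragments,
themselves arranged on a larger triangular lattice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "PatchLayout",
    "MultiScaleLayout",
    "build_grid",
    "patch_mask",
    "hexagon_mask",
    "multiscale_mask",
    "init_fields",
    "build_death_field",
    "build_multiscale_layout",
]

SQRT3 = math.sqrt(3.0)

# Guard against cases like 2.2/0.02 = 110.00000000000001 rounding up.
_CEIL_EPS = 1e-9


def _iceil(x: float) -> int:
    return int(math.ceil(x - _CEIL_EPS))


@dataclass(frozen=True, eq=False)
class GridSpec:
    """Uniform periodic grid with node spacing ``dx``.

    The tile is periodic in both directions with period ``width = nx*dx`` and
    ``height = ny*dx``; node coordinates are cell-based, so the node to the
    "right" of ``x[-1]`` is ``x[0]`` again.
    """

    dx: float
    nx: int
    ny: int
    x: np.ndarray
    y: np.ndarray

    @property
    def width(self) -> float:
        return self.nx * self.dx

    @property
    def height(self) -> float:
        return self.ny * self.dx

    @property
    def shape(self) -> tuple[int, int]:
        """Field shape (ny, nx): rows index y, columns index x."""
        return (self.ny, self.nx)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)


@dataclass(frozen=True)
class PatchLayout:
    """Single-scale layout: discs of radius ``r`` on a triangular lattice of
    spacing ``s``; uniform densities ``rho_int`` inside / ``rho_ext`` outside
    (fractions of carrying capacity)."""

    s: float
    r: float
    rho_int: float
    rho_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.s <= 0 or self.r <= 0:
            raise ValueError("s and r must be positive")
        if self.rho_int < 0 or self.rho_ext < 0:
            raise ValueError("densities must be non-negative")
        if 2 * self.r > self.s:
            warnings.warn(
                f"patches overlap (2r = {2 * self.r} > s = {self.s}); "
                "overlapping regions take rho_int once",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MultiScaleLayout:
    """Two-scale layout: hexagonal macro-fragments (circumradius ``R``) on a
    triangular macro-lattice of spacing ``S``, each filled with a micro-lattice
    of discs described by ``micro``."""

    S: float
    R: float
    micro: PatchLayout

    def __post_init__(self) -> None:
        if not (self.R < self.S / 2):
            raise ValueError("macro-hexagons must not overlap: require R < S/2")
        if not (self.micro.s < 2 * self.R):
            raise ValueError("micro-lattice spacing must fit inside the hexagon")


def build_grid(s: float, dx: float) -> GridSpec:
    """Grid for a periodic tile of an ``s``-spaced triangular lattice.

    ``nx = ceil(s/dx)``, ``ny = ceil(sqrt(3)*s/dx)``; nodes at
    ``x_i = -s/2 + dx*(i-1)`` and ``y_j = -ceil((sqrt(3)/2)*s/dx)*dx + dx*(j-1)``,
    giving a tile of approximately ``s x sqrt(3)*s``.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if s <= dx:
        raise ValueError(f"lattice spacing s={s} must exceed dx={dx}")
    nx = _iceil(s / dx)
    ny = _iceil(SQRT3 * s / dx)
    y0 = -_iceil((SQRT3 / 2.0) * s / dx) * dx
    x = -s / 2.0 + dx * np.arange(nx)
    y = y0 + dx * np.arange(ny)
    return GridSpec(dx=dx, nx=nx, ny=ny, x=x, y=y)


def _min_image(d: np.ndarray, period: float) -> np.ndarray:
    """Signed displacement reduced to the nearest periodic image."""
    return d - period * np.round(d / period)


def _centers(grid: GridSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """The two lattice points of the rectangular unit cell: the tile centre
    and the corner point (half a period away in both directions)."""
    return (0.0, 0.0), (grid.width / 2.0, grid.height / 2.0)


def patch_mask(grid: GridSpec, r: float) -> np.ndarray:
    """Boolean field marking nodes within distance ``r`` (inclusive) of the
    tile centre or of the tile corners, in the periodic metric.

    As ``dx -> 0`` the marked area converges to ``2*pi*r**2`` (two whole
    discs per tile).
    """
    if r <= 0:
        raise ValueError("patch radius must be positive")
    if 2 * r > min(grid.width, grid.height):
        warnings.warn(
            f"patch radius {r} exceeds half the tile; periodic images overlap",
            stacklevel=2,
        )
    X, Y = grid.meshgrid()
    mask = np.zeros(grid.shape, dtype=bool)
    for cx, cy in _centers(grid):
        dxs = _min_image(X - cx, grid.width)
        dys = _min_image(Y - cy, grid.height)
        mask |= dxs**2 + dys**2 <= r**2
    return mask


def _in_hexagon(dxs: np.ndarray, dys: np.ndarray, R: float):
    """Membership test for a regular flat-topped hexagon of circumradius R
    centred at the origin (boundary-inclusive)."""
    apothem = SQRT3 * R / 2.0
    inside = np.abs(dys) <= apothem
    inside &= np.abs(SQRT3 / 2.0 * dxs + 0.5 * dys) <= apothem
    inside &= np.abs(SQRT3 / 2.0 * dxs - 0.5 * dys) <= apothem
    return inside


def hexagon_mask(grid: GridSpec, R: float, center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Nodes inside a regular flat-topped hexagon of circumradius ``R``
    centred at ``center``, in the periodic metric."""
    X, Y = grid.meshgrid()
    dxs = _min_image(X - center[0], grid.width)
    dys = _min_image(Y - center[1], grid.height)
    return _in_hexagon(dxs, dys, R)


def _micro_disc_centers(layout: MultiScaleLayout):
    """Triangular-lattice micro-disc centres (offsets from a macro centre)
    whose centres fall inside the macro-hexagon."""
    s, R = layout.micro.s, layout.R
    row_h = SQRT3 / 2.0 * s
    jmax = int(math.floor((SQRT3 * R / 2.0) / row_h)) + 1
    centers = []
    for j in range(-jmax, jmax + 1):
        oy = j * row_h
        xoff = (s / 2.0) if (j % 2) else 0.0
        imax = int(math.floor((R + s) / s)) + 1
        for i in range(-imax, imax + 1):
            ox = xoff + i * s
            if _in_hexagon(np.array(ox), np.array(oy), R):
                centers.append((ox, oy))
    return centers


def multiscale_mask(grid: GridSpec, layout: MultiScaleLayout) -> np.ndarray:
    """Initial-population mask for the two-scale layout: the union over the
    tile's two macro-hexagons of the whole micro-discs whose centres lie in
    the hexagon.  Every micro-fragment is identical (same radius and density
    as in the single-scale layouts); the hexagon delimits which lattice sites
    carry a fragment, not the fragment shapes themselves.
    """
    X, Y = grid.meshgrid()
    offsets = _micro_disc_centers(layout)
    r2 = layout.micro.r**2
    mask = np.zeros(grid.shape, dtype=bool)
    for cx, cy in _centers(grid):
        dxs = _min_image(X - cx, grid.width)
        dys = _min_image(Y - cy, grid.height)
        for ox, oy in offsets:
            mask |= (dxs - ox) ** 2 + (dys - oy) ** 2 <= r2
    return mask


def init_fields(
    grid: GridSpec, mask: np.ndarray, rho_int: float, rho_ext: float, n: int
) -> np.ndarray:
    """Initial genotype stack: every genotype gets an equal share, so
    ``Psi_k = rho_int/n`` on the mask and ``rho_ext/n`` elsewhere, giving an
    initial mean dispersal ability of ``(1 + n)/2`` wherever the population
    is non-empty."""
    if rho_int < 0 or rho_ext < 0:
        raise ValueError("densities must be non-negative")
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("n must be a positive integer")
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    layer = np.where(mask, rho_int / n, rho_ext / n)
    return np.broadcast_to(layer, (n, *grid.shape)).copy()


def build_death_field(
    grid: GridSpec, mask: np.ndarray, delta_int: float, delta_ext: float
) -> np.ndarray:
    """Piecewise-constant death-rate field: ``delta_int`` on the mask (habitat
    islands), ``delta_ext`` elsewhere."""
    if delta_int <= 0 or delta_ext <= 0:
        raise ValueError("death rates must be positive")
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    return np.where(mask, float(delta_int), float(delta_ext))


def build_multiscale_layout(
    layout: MultiScaleLayout,
    dx: float,
    n: int,
    match_population: float | None = None,
) -> tuple[GridSpec, np.ndarray]:
    """Grid and initial stack for a two-scale layout.

    The tile spans one macro-lattice cell (``S x sqrt(3)*S``).  If
    ``match_population`` is given, the interior density is rescaled so the
    total initial population equals that value (used to give the coarse and
    fine variants identical starting populations).
    """
    grid = build_grid(layout.S, dx)
    mask = multiscale_mask(grid, layout)
    rho = layout.micro.rho_int
    count = int(mask.sum())
    if count == 0:
        warnings.warn("multiscale mask is empty", stacklevel=2)
    if match_population is not None:
        if count == 0:
            raise ValueError("cannot match population on an empty mask")
        rho = match_population / (count * dx**2)
    fields = init_fields(grid, mask, rho, layout.micro.rho_ext, n)
    return grid, fields
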