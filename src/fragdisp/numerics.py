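"""Method-of-lines integration of the multi-genotype dynamics.

Space is discretized on the periodic tile with the compact 9-point Laplacian
stencil; the resulting ODE system is advanced with an adaptive embedded
Runge-Kutta 5(4) pair (Dormand-Prince, via :class:`scipy.integrate.RK45`).
Termination monitors -- spatial uniformity of the slowest genotype,
extinction of the total population, and stagnation of the time derivative --
are evaluated at every accepted step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import RK45

from . import _kernels
from .geometry import GridSpec
from .model import InheritanceKernel, ModelParams, birth_term_general
from .observables import SummarySeries, sigma_over_mean

__all__ = [
    "SimulatorState",
    "TerminationRule",
    "IntegrationResult",
    "StiffFailureError",
    "DEFAULT_RULES",
    "laplacian_9pt",
    "rhs",
    "check_termination",
    "integrate",
]


class StiffFailureError(RuntimeError):
    """Raised when the adaptive step size underflows."""


@dataclass(frozen=True)
class TerminationRule:
    """A stopping monitor.

    kind
        ``"uniformity"``: stop when std/mean of the genotype-1 field drops
        below the threshold (default 1e-3) -- the slowest dispersers have
        reached a nearly uniform density, so the run is effectively over.
        ``"extinction"``: stop when the total population P drops below the
        threshold (default 1e-4).
        ``"stagnation"``: stop when the signed node sum
        ``sum_nodes dPsi_k/dt * dx**2`` (= dP_k/dt, the growth rate of the
        genotype total) is below the threshold (default 0.1) for every
        genotype -- the habitat has saturated and no genotype is still
        gaining population appreciably.  One-sided by construction: it fires
        as net growth levels off, immediately after saturation, even while
        slower redistributive drifts continue.
        ``"quiescence"``: the two-sided variant, ``|dP_k/dt|`` below the
        threshold (default 0.1) for all genotypes.  Unlike stagnation it is
        safe for runs whose genotype totals transiently shrink (it will not
        fire during an early Allee-loss dip); used as the stopping monitor
        for layouts too large for the uniformity criterion to be practical.
    """

    kind: str
    threshold: float

    _DEFAULTS = {"uniformity": 1e-3, "extinction": 1e-4, "stagnation": 0.1, "quiescence": 0.1}
    _OUTCOMES = {
        "uniformity": "uniform",
        "extinction": "extinct",
        "stagnation": "stagnant",
        "quiescence": "stagnant",
    }

    @classmethod
    def default(cls, kind: str) -> "TerminationRule":
        if kind not in cls._DEFAULTS:
            raise ValueError(f"unknown termination rule {kind!r}")
        return cls(kind, cls._DEFAULTS[kind])

    @property
    def outcome(self) -> str:
        return self._OUTCOMES[self.kind]


DEFAULT_RULES = (TerminationRule.default("uniformity"), TerminationRule.default("extinction"))


@dataclass
class SimulatorState:
    """Full state of a simulation: time, genotype stack, parameters, grid and
    (possibly spatially varying) death field."""

    t: float
    fields: np.ndarray  # (n, ny, nx), non-negative
    params: ModelParams
    grid: GridSpec
    death: np.ndarray | None = None  # (ny, nx); uniform params.delta if None

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        expected = (self.params.n, *self.grid.shape)
        if self.fields.shape != expected:
            raise ValueError(f"fields shape {self.fields.shape}, expected {expected}")
        if self.death is None:
            self.death = np.full(self.grid.shape, float(self.params.delta))
        else:
            self.death = np.asarray(self.death, dtype=float)
            if self.death.shape != self.grid.shape:
                raise ValueError("death field shape does not match grid")

    def copy(self) -> "SimulatorState":
        return SimulatorState(
            t=self.t,
            fields=self.fields.copy(),
            params=self.params,
            grid=self.grid,
            death=self.death.copy(),
        )


def laplacian_9pt(f: np.ndarray, dx: float) -> np.ndarray:
    """Compact 9-point Laplacian with periodic wrap-around:

    ``(4*(N+S+E+W) + (NE+NW+SE+SW) - 20*C) / (6*dx**2)``

    The weights sum to zero and the stencil is symmetric, so the field sum of
    the output vanishes to machine precision (discrete mass conservation).
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("field contains non-finite values")
    N = np.roll(f, -1, axis=0)
    S = np.roll(f, 1, axis=0)
    E = np.roll(f, -1, axis=1)
    W = np.roll(f, 1, axis=1)
    NE = np.roll(N, -1, axis=1)
    NW = np.roll(N, 1, axis=1)
    SE = np.roll(S, -1, axis=1)
    SW = np.roll(S, 1, axis=1)
    return (4.0 * (N + S + E + W) + NE + NW + SE + SW - 20.0 * f) / (6.0 * dx * dx)


def rhs(state: SimulatorState, kernel: InheritanceKernel | None = None) -> np.ndarray:
    """Right-hand side of the dynamics for every genotype:

    ``dPsi_k/dt = (k**2/4) * lap(Psi_k) + (beta*Psi*(1 - Psi) - delta(x,y)) * Psi_k``

    With an explicit inheritance kernel the birth term is the general pairing
    sum instead; for the Mendelian kernel the two paths coincide.
    """
    p = state.params
    fields = state.fields
    if kernel is None:
        out = np.empty_like(fields)
        _kernels.rhs_kernel(
            fields, p.diffusivities, p.beta, state.death, state.grid.dx, out
        )
        return out
    births = birth_term_general(np.clip(fields, 0.0, None), kernel, p.beta)
    out = births - state.death * fields
    for k in range(p.n):
        out[k] += p.diffusivities[k] * laplacian_9pt(fields[k], state.grid.dx)
    return out


def rhs_reference(state: SimulatorState) -> np.ndarray:
    """Pure-numpy Mendelian-path right-hand side (readable reference for the
    compiled kernel used by :func:`rhs`)."""
    p = state.params
    total = state.fields.sum(axis=0)
    growth = p.beta * total * (1.0 - total) - state.death
    out = growth * state.fields
    for k in range(p.n):
        out[k] += p.diffusivities[k] * laplacian_9pt(state.fields[k], state.grid.dx)
    return out


def check_termination(
    fields: np.ndarray,
    dfields_dt: np.ndarray | None,
    dx: float,
    rules,
) -> str | None:
    """Evaluate termination monitors; returns the outcome flag of the first
    rule that fires (extinction checked first) or None."""
    dx2 = dx * dx
    by_kind = {r.kind: r for r in rules}
    if "extinction" in by_kind:
        P = fields.sum() * dx2
        if P < by_kind["extinction"].threshold:
            return "extinct"
    if "uniformity" in by_kind:
        if sigma_over_mean(fields[0]) < by_kind["uniformity"].threshold:
            return "uniform"
    if dfields_dt is not None and ("stagnation" in by_kind or "quiescence" in by_kind):
        rates = dfields_dt.sum(axis=tuple(range(1, dfields_dt.ndim))) * dx2
        if "stagnation" in by_kind and np.all(rates < by_kind["stagnation"].threshold):
            return "stagnant"
        if "quiescence" in by_kind and np.all(np.abs(rates) < by_kind["quiescence"].threshold):
            return "stagnant"
    return None


@dataclass
class IntegrationResult:
    series: SummarySeries
    outcome: str
    state: SimulatorState
    snapshots: list[tuple[float, np.ndarray]] = field(default_factory=list)
    n_clipped: int = 0
    min_density: float = 0.0
    n_steps: int = 0


def integrate(
    state: SimulatorState,
    t_max: float,
    rules=DEFAULT_RULES,
    *,
    kernel: InheritanceKernel | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    snapshot_times=None,
    check_initial: bool = False,
) -> IntegrationResult:
    """Advance the state to ``t_max`` or until a termination rule fires.

    Uses the embedded Dormand-Prince 5(4) pair with per-step error control on
    the stacked field vector.  After each accepted step, negative density
    excursions (floating-point noise around the invariant manifold
    ``Psi_k = 0``) are clipped to zero and counted; termination rules are then
    evaluated on the accepted state (no dense-output root finding, so the
    reported stop time is accurate to one step).

    Summaries are recorded at every accepted step; field snapshots are taken
    at the first accepted step at or past each entry of ``snapshot_times``.
    """
    if t_max <= state.t:
        raise ValueError("t_max must exceed the current state time")
    state = state.copy()
    p = state.params
    shape = state.fields.shape
    dx = state.grid.dx
    dx2 = dx * dx
    diff = p.diffusivities
    death = state.death

    def f(t, y):
        psi = y.reshape(shape)
        out = np.empty(shape)
        _kernels.rhs_kernel(psi, diff, p.beta, death, dx, out)
        return out.ravel()

    def f_general(t, y):
        psi = y.reshape(shape)
        st = replace_fields(psi, t)
        return rhs(st, kernel).ravel()

    def replace_fields(psi, t):
        s = state.copy()
        s.fields = psi
        s.t = t
        return s

    fun = f if kernel is None else f_general

    times = [state.t]
    Pks = [state.fields.sum(axis=(1, 2)) * dx2]
    sigmas = [sigma_over_mean(state.fields[0])]
    snapshots: list[tuple[float, np.ndarray]] = []
    snap_times = sorted(snapshot_times) if snapshot_times is not None else []
    snap_idx = 0
    n_clipped = 0
    min_density = float(state.fields.min())
    outcome = None

    if check_initial:
        outcome = check_termination(state.fields, None, dx, rules)
        if outcome is not None:
            series = SummarySeries(
                t=np.array(times), Pk=np.array(Pks), sigma_ratio=np.array(sigmas), a0=p.a0
            )
            return IntegrationResult(series=series, outcome=outcome, state=state)

    solver = RK45(fun, state.t, state.fields.ravel().copy(), t_max, rtol=rtol, atol=atol)
    n_steps = 0
    while outcome is None and solver.status == "running":
        solver.step()
        if solver.status == "failed":
            raise StiffFailureError(f"step-size underflow at t={solver.t:.6g}")
        n_steps += 1
        y = solver.y
        ymin = y.min()
        if ymin < min_density:
            min_density = float(ymin)
        if ymin < 0:
            neg = y < 0
            n_clipped += int(neg.sum())
            y[neg] = 0.0
        fields = y.reshape(shape)
        Pk = fields.sum(axis=(1, 2)) * dx2
        times.append(solver.t)
        Pks.append(Pk)
        sigmas.append(sigma_over_mean(fields[0]))
        while snap_idx < len(snap_times) and solver.t >= snap_times[snap_idx]:
            snapshots.append((solver.t, fields.copy()))
            snap_idx += 1
        dfields = solver.f.reshape(shape) if solver.f is not None else None
        outcome = check_termination(fields, dfields, dx, rules)

    if outcome is None:
        outcome = "t_max_reached"

    state.t = float(solver.t)
    state.fields = solver.y.reshape(shape).copy()
    series = SummarySeries(
        t=np.array(times),
        Pk=np.array(Pks),
        sigma_ratio=np.array(sigmas),
        a0=p.a0,
    )
    return IntegrationResult(
        series=series,
        outcome=outcome,
        state=state,
        snapshots=snapshots,
        n_clipped=n_clipped,
        min_density=min_density,
        n_steps=n_steps,
    )
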