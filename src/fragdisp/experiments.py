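"""The five numerical test cases (A-E) as reproducible drivers.

A  "habitat islands": population fragments coincide with discs where the
   death rate differs from the exterior; sweeps lattice spacing s and the
   exterior death rate.  Reports the mean dispersal ability when the
   stagnation monitor first fires (soon after the habitat saturates).
B  homogeneous environment; sweeps lattice spacing s across (beta, delta).
C  fragment size vs density trade-off: radius r varies with interior density
   rho_int = 0.1273 / r**2 so the initial overall density is unchanged.
D  inverted layout: a saturated domain with freshly depopulated discs.
E  two-scale fragmentation: hexagonal macro-fragments subdivided coarsely
   (s=2.2, r=1.0) or finely (s=1.1, r=0.5), equal total initial population.

There is no randomness anywhere in the model: identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    MultiScaleLayout,
    PatchLayout,
    build_grid,
    build_multiscale_layout,
    init_fields,
    build_death_field,
    multiscale_mask,
    patch_mask,
)
from .model import ModelParams
from .numerics import (
    IntegrationResult,
    SimulatorState,
    TerminationRule,
    integrate,
)
from .observables import mean_dispersal, totals

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "preset",
    "run",
    "sweep",
    "experimentA_final_abar",
    "experimentA_drain",
    "plot_sweep",
    "RHO_REF",
]

#: Reference interior density (about 0.4/pi: each full disc of radius 1
#: carries an initial population of 0.4).
RHO_REF = 0.1273


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully resolved simulation configuration (one point of a sweep).

    ``sweep_ranges`` records the ranges over which the preset's independent
    variable and environmental parameters were varied; it does not affect a
    single run.
    """

    experiment: str
    n: int = 5
    dx: float = 0.02
    s: float | None = None
    r: float | None = None
    rho_int: float | None = None
    rho_ext: float = 0.0
    beta: float = 380.0
    delta: float = 36.0
    delta_int: float | None = None  # Experiment A habitat-island death rates
    delta_ext: float | None = None
    S: float | None = None  # Experiment E macro-lattice
    R: float | None = None
    variant: str | None = None  # "coarse" | "fine"
    t_max: float = 50.0
    rtol: float = 1e-6
    atol: float = 1e-9
    rules: tuple[str, ...] = ("extinction", "uniformity")
    sweep_ranges: dict = field(default_factory=dict, compare=False)

    def termination_rules(self) -> tuple[TerminationRule, ...]:
        return tuple(TerminationRule.default(k) for k in self.rules)


_PRESETS: dict[str, ExperimentConfig] = {
    "A": ExperimentConfig(
        experiment="A",
        s=2.2,
        r=1.0,
        rho_int=RHO_REF,
        rho_ext=0.0,
        beta=365.0,
        delta=35.0,
        delta_int=35.0,
        delta_ext=35.0,
        rules=("extinction", "stagnation"),
        sweep_ranges={"s": (2.0, 2.5), "delta_ext": (10.0, 70.0)},
    ),
    "B": ExperimentConfig(
        experiment="B",
        s=2.15,
        r=1.0,
        rho_int=RHO_REF,
        rho_ext=0.0,
        beta=380.0,
        delta=36.0,
        sweep_ranges={"s": (2.0, 2.5), "beta": (350.0, 400.0), "delta": (35.0, 39.0)},
    ),
    "C": ExperimentConfig(
        experiment="C",
        s=2.0,
        r=0.5,
        rho_int=None,  # resolved as RHO_REF / r**2
        rho_ext=0.0,
        beta=365.0,
        delta=50.0,
        sweep_ranges={"r": (0.1, 0.9), "beta": (350.0, 380.0), "delta": (45.0, 60.0)},
    ),
    "D": ExperimentConfig(
        experiment="D",
        s=2.2,
        r=1.0,
        rho_int=0.0,
        rho_ext=1.0,
        beta=370.0,
        delta=45.0,
        sweep_ranges={"s": (2.0, 2.5), "beta": (360.0, 380.0), "delta": (40.0, 55.0)},
    ),
    "E": ExperimentConfig(
        experiment="E",
        dx=0.04,
        variant="coarse",
        s=2.2,
        r=1.0,
        rho_int=RHO_REF,
        rho_ext=0.0,
        beta=385.0,
        delta=37.0,
        S=13.2,
        R=5.0,
        rules=("extinction", "quiescence"),
        sweep_ranges={"variant": ("coarse", "fine")},
    ),
}

#: Experiment E micro-lattice parameters per variant.
E_VARIANTS = {"coarse": (2.2, 1.0), "fine": (1.1, 0.5)}


def preset(experiment_id: str) -> ExperimentConfig:
    """The published parameterization of one test case (A-E)."""
    try:
        return _PRESETS[experiment_id.upper()]
    except KeyError:
        raise ValueError(f"unknown experiment {experiment_id!r}; expected A-E") from None


def resolve_rho_int(config: ExperimentConfig) -> float:
    """Interior density, applying Experiment C's constant-overall-density
    rule ``rho_int(r) = 0.1273 / r**2`` when none is set explicitly."""
    if config.rho_int is not None:
        return config.rho_int
    if config.experiment.upper() == "C" and config.r:
        return RHO_REF / config.r**2
    raise ValueError("rho_int is unset and no density rule applies")


def _fine_variant_rho(config: ExperimentConfig) -> float:
    """Experiment E fine-variant interior density, fixed by requiring the
    same total initial population as the coarse variant at the same dx."""
    s_c, r_c = E_VARIANTS["coarse"]
    s_f, r_f = E_VARIANTS["fine"]
    grid = build_grid(config.S, config.dx)
    coarse = multiscale_mask(grid, MultiScaleLayout(config.S, config.R, PatchLayout(s_c, r_c, RHO_REF)))
    fine = multiscale_mask(grid, MultiScaleLayout(config.S, config.R, PatchLayout(s_f, r_f, RHO_REF)))
    return RHO_REF * int(coarse.sum()) / int(fine.sum())


def build_initial_state(config: ExperimentConfig) -> SimulatorState:
    """Construct grid, initial genotype stack and death field for a config."""
    exp = config.experiment.upper()
    params = ModelParams(n=config.n, beta=config.beta, delta=config.delta)
    if exp == "E":
        if config.variant not in E_VARIANTS:
            raise ValueError("Experiment E requires variant 'coarse' or 'fine'")
        s, r = E_VARIANTS[config.variant]
        rho = RHO_REF if config.variant == "coarse" else _fine_variant_rho(config)
        layout = MultiScaleLayout(config.S, config.R, PatchLayout(s, r, rho))
        grid, fields = build_multiscale_layout(layout, config.dx, config.n)
        return SimulatorState(t=0.0, fields=fields, params=params, grid=grid)

    grid = build_grid(config.s, config.dx)
    mask = patch_mask(grid, config.r)
    rho_int = resolve_rho_int(config)
    fields = init_fields(grid, mask, rho_int, config.rho_ext, config.n)
    death = None
    if config.delta_int is not None or config.delta_ext is not None:
        d_int = config.delta_int if config.delta_int is not None else config.delta
        d_ext = config.delta_ext if config.delta_ext is not None else config.delta
        death = build_death_field(grid, mask, d_int, d_ext)
    return SimulatorState(t=0.0, fields=fields, params=params, grid=grid, death=death)


@dataclass
class RunResult:
    config: ExperimentConfig
    result: IntegrationResult

    @property
    def series(self):
        return self.result.series

    @property
    def outcome(self) -> str:
        return self.result.outcome

    @property
    def final_a_bar(self) -> float | None:
        """Final mean dispersal ability; missing for extinct runs."""
        if self.outcome == "extinct":
            return None
        return self.series.final_a_bar()


def run(config: ExperimentConfig, snapshot_times=None, **overrides) -> RunResult:
    """Build the configured geometry and integrate to termination."""
    if overrides:
        config = replace(config, **overrides)
    state = build_initial_state(config)
    result = integrate(
        state,
        config.t_max,
        config.termination_rules(),
        rtol=config.rtol,
        atol=config.atol,
        snapshot_times=snapshot_times,
    )
    return RunResult(config=config, result=result)


def sweep(config: ExperimentConfig, grid: dict) -> pd.DataFrame:
    """Run every combination of the supplied parameter values.

    ``grid`` maps config field names to iterables, e.g.
    ``{"s": [2.0, 2.1], "beta": [370], "delta": [36]}``.  One tidy row per
    run; failures are recorded per row rather than aborting the sweep.
    Extinct runs carry a missing final mean dispersal ability.
    """
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        row = dict(overrides)
        try:
            rr = run(config, **overrides)
            row.update(
                beta=rr.config.beta,
                delta=rr.config.delta,
                outcome=rr.outcome,
                a_bar_final=np.nan if rr.final_a_bar is None else rr.final_a_bar,
                t_stop=rr.series.t[-1],
            )
        except Exception as exc:  # per-row failure, not fatal
            row.update(outcome=f"error: {exc}", a_bar_final=np.nan, t_stop=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def experimentA_final_abar(config: ExperimentConfig, **overrides) -> float | None:
    """Mean dispersal ability at the first firing of the stagnation monitor
    (not a steady state: the value attained soon after the habitat
    saturates, before slow heterogeneity-driven drift)."""
    if overrides:
        config = replace(config, **overrides)
    if "stagnation" not in config.rules:
        config = replace(config, rules=(*config.rules, "stagnation"))
    rr = run(config)
    if rr.outcome == "extinct":
        return None
    return rr.final_a_bar


def experimentA_drain(
    config: ExperimentConfig, t_final: float = 6.0, **overrides
) -> dict:
    """Run a habitat-islands configuration to stagnation, then continue to
    ``t_final`` to expose the slow drain of fast dispersers into the more
    lethal region.

    Returns the saturation time, the mean dispersal ability there and at
    ``t_final``, and their ratio.
    """
    if overrides:
        config = replace(config, **overrides)
    config = replace(config, rules=("extinction", "stagnation"))
    rr = run(config)
    if rr.outcome != "stagnant":
        raise RuntimeError(f"expected stagnation before t_max, got {rr.outcome!r}")
    t_sat = float(rr.series.t[-1])
    abar_sat = rr.final_a_bar
    cont = integrate(
        rr.result.state,
        t_final,
        (TerminationRule.default("extinction"),),
        rtol=config.rtol,
        atol=config.atol,
    )
    abar_final = cont.series.final_a_bar()
    ratio = None
    if abar_sat and abar_final:
        ratio = abar_final / abar_sat
    return {
        "t_sat": t_sat,
        "a_bar_sat": abar_sat,
        "a_bar_final": abar_final,
        "ratio": ratio,
        "outcome": cont.outcome,
    }


def plot_sweep(df: pd.DataFrame, x: str, out_path=None):
    """Final mean dispersal ability against the independent variable, one
    curve per (beta, delta) pair; extinct runs are omitted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    surv = df[df["outcome"].isin(["uniform", "stagnant", "t_max_reached"])]
    for (b, d), sub in surv.groupby(["beta", "delta"]):
        sub = sub.sort_values(x)
        ax.plot(sub[x], sub["a_bar_final"], "o-", label=f"$\\beta$={b:g}, $\\delta$={d:g}")
    ax.set_xlabel(x)
    ax.set_ylabel(r"final $\bar{a}$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
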