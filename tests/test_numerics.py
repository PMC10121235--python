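"""Discretization, time integration and termination-monitor behaviour."""

import numpy as np
import pytest

from fragdisp.geometry import build_grid
from fragdisp.model import ModelParams, fixed_points, make_mendelian_kernel
from fragdisp.numerics import (
    SimulatorState,
    TerminationRule,
    check_termination,
    integrate,
    laplacian_9pt,
    rhs,
    rhs_reference,
)
from fragdisp.validation import wellmixed_oracle


class TestLaplacian:
    def test_constant_field_in_null_space(self):
        out = laplacian_9pt(np.full((12, 9), 3.7), 0.1)
        assert np.abs(out).max() < 1e-11

    def test_plane_wave_matches_fourier_symbol(self, small_grid):
        g = small_grid
        X, _ = g.meshgrid()
        field = np.cos(2 * np.pi * X / g.width)
        alpha = 2 * np.pi * g.dx / g.width
        # symbol of (4*orth + diag - 20*c)/(6 dx^2) at (alpha, 0)
        lam = (-20 + 8 * np.cos(alpha) + 8 + 4 * np.cos(alpha)) / (6 * g.dx**2)
        out = laplacian_9pt(field, g.dx)
        assert np.abs(out - lam * field).max() < 1e-10 * abs(lam)

    def test_field_sum_vanishes_under_periodicity(self, rng):
        f = rng.random((17, 23))
        out = laplacian_9pt(f, 0.05)
        assert abs(out.sum()) < 1e-10 * np.abs(out).max()

    def test_nonfinite_input_rejected(self):
        f = np.zeros((4, 4))
        f[0, 0] = np.nan
        with pytest.raises(ValueError):
            laplacian_9pt(f, 0.1)


class TestRHS:
    def test_uniform_state_reduces_to_ode(self, small_grid, params):
        psi0 = 0.4
        fields = np.full((5, *small_grid.shape), psi0 / 5)
        st = SimulatorState(0.0, fields, params, small_grid)
        out = rhs(st)
        expected = (params.beta * psi0 * (1 - psi0) - params.delta) * psi0 / 5
        assert np.abs(out - expected).max() < 1e-9

    def test_compiled_kernel_matches_numpy_reference(self, small_grid, params, rng):
        fields = rng.random((5, *small_grid.shape)) * 0.2
        st = SimulatorState(0.0, fields, params, small_grid)
        assert np.abs(rhs(st) - rhs_reference(st)).max() < 1e-12

    def test_general_kernel_path_matches_mendelian_path(self, small_grid, params, rng):
        fields = rng.random((5, *small_grid.shape)) * 0.2
        st = SimulatorState(0.0, fields, params, small_grid)
        ker = make_mendelian_kernel(5)
        assert np.abs(rhs(st) - rhs(st, ker)).max() < 1e-12

    def test_saturated_uniform_state_is_stationary(self, small_grid, params):
        psi_plus = fixed_points(params.beta, params.delta).psi_plus
        fields = np.full((5, *small_grid.shape), psi_plus / 5)
        st = SimulatorState(0.0, fields, params, small_grid)
        assert np.abs(rhs(st)).max() < 1e-9

    def test_shape_mismatch_rejected(self, small_grid, params, rng):
        fields = rng.random((5, *small_grid.shape)) * 0.2
        st = SimulatorState(0.0, fields, params, small_grid)
        with pytest.raises(ValueError):
            rhs(st, make_mendelian_kernel(3))


class TestIntegrate:
    def test_pure_death_is_exponential(self, small_grid):
        p = ModelParams(n=2, beta=0.0, delta=2.0)
        fields = np.full((2, *small_grid.shape), 0.3)
        res = integrate(
            SimulatorState(0.0, fields, p, small_grid), 0.5, rules=(), rtol=1e-8, atol=1e-11
        )
        P0, P1 = res.series.P[0], res.series.P[-1]
        assert P1 == pytest.approx(P0 * np.exp(-2.0 * 0.5), rel=1e-6)

    def test_pure_diffusion_conserves_mass(self, small_grid, rng):
        p = ModelParams(n=2, beta=0.0, delta=0.0)
        fields = rng.random((2, *small_grid.shape))
        res = integrate(SimulatorState(0.0, fields, p, small_grid), 0.3, rules=())
        assert abs(res.series.P[-1] - res.series.P[0]) < 1e-10 * res.series.P[0]

    def test_uniform_ic_matches_wellmixed_oracle(self, small_grid, params):
        fields = np.full((5, *small_grid.shape), 0.1)
        st = SimulatorState(0.0, fields, params, small_grid)
        res = integrate(st, 0.5, rules=(), rtol=1e-10, atol=1e-12)
        oracle = wellmixed_oracle(params.beta, params.delta, [0.1] * 5, [0.0, 0.5])[-1]
        assert np.abs(res.state.fields - oracle[:, None, None]).max() < 1e-8

    def test_uniform_ic_conserves_genotype_frequencies(self, small_grid, params):
        fields = np.stack([np.full(small_grid.shape, v) for v in (0.05, 0.1, 0.15, 0.1, 0.1)])
        st = SimulatorState(0.0, fields, params, small_grid)
        res = integrate(st, 0.5, rules=())
        ab = res.series.a_bar
        assert np.abs(ab - ab[0]).max() < 1e-7

    def test_densities_stay_nonnegative(self):
        g = build_grid(2.0, 0.1)
        from fragdisp.geometry import init_fields, patch_mask

        fields = init_fields(g, patch_mask(g, 0.7), 0.1273, 0.0, 3)
        p = ModelParams(n=3, beta=380.0, delta=36.0)
        res = integrate(SimulatorState(0.0, fields, p, g), 0.05, rules=())
        assert res.min_density > -1e-9
        assert res.state.fields.min() >= 0.0

    def test_reruns_are_bit_identical(self, small_grid, params, rng):
        fields = rng.random((5, *small_grid.shape)) * 0.2
        runs = [
            integrate(SimulatorState(0.0, fields.copy(), params, small_grid), 0.1, rules=())
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].state.fields, runs[1].state.fields)
        assert np.array_equal(runs[0].series.t, runs[1].series.t)

    def test_t_max_must_advance(self, small_grid, params):
        st = SimulatorState(1.0, np.zeros((5, *small_grid.shape)), params, small_grid)
        with pytest.raises(ValueError):
            integrate(st, 0.5)


class TestTermination:
    rules = tuple(TerminationRule.default(k) for k in ("uniformity", "extinction", "stagnation"))

    def test_uniform_positive_field_fires_uniformity(self):
        fields = np.full((2, 4, 4), 0.3)
        assert check_termination(fields, None, 0.1, self.rules) == "uniform"

    def test_zero_fields_fire_extinction(self):
        fields = np.zeros((2, 4, 4))
        assert check_termination(fields, None, 0.1, self.rules) == "extinct"

    def test_stationary_saturated_state_fires_stagnation(self, small_grid, params):
        psi_plus = fixed_points(params.beta, params.delta).psi_plus
        fields = np.full((5, *small_grid.shape), psi_plus / 5)
        st = SimulatorState(0.0, fields, params, small_grid)
        d = rhs(st)
        only_stag = (TerminationRule.default("stagnation"),)
        assert check_termination(fields, d, small_grid.dx, only_stag) == "stagnant"

    def test_growing_population_does_not_fire_stagnation(self):
        # signed per-genotype growth rates above threshold -> no fire
        fields = np.full((2, 4, 4), 0.2)
        growing = np.full_like(fields, 1.0)
        only_stag = (TerminationRule.default("stagnation"),)
        assert check_termination(fields, growing, 0.1, only_stag) is None

    def test_quiescence_is_two_sided(self):
        fields = np.full((2, 4, 4), 0.5)
        shrinking = np.full_like(fields, -5.0)
        stag = (TerminationRule.default("stagnation"),)
        quie = (TerminationRule.default("quiescence"),)
        # a rapidly shrinking population satisfies the one-sided rule ...
        assert check_termination(fields, shrinking, 0.1, stag) == "stagnant"
        # ... but not the two-sided one
        assert check_termination(fields, shrinking, 0.1, quie) is None

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            TerminationRule.default("nonsense")
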