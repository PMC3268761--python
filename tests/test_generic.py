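"""Coarse-grained polarity model: right-hand side, presets, adaptation."""

import numpy as np
import pytest
from scipy.special import expit

from polarsim.geometry import Field, make_grid, surface_average
from polarsim.generic import (
    CascadeSpec,
    GenericStageParams,
    GenericStageState,
    generic_rhs,
    hill,
    make_preset,
    scale_speed,
    simulate_generic,
)
from polarsim.inputs import BatchedInputProcess, GradientSpec, InputProcess, NoiseSpec


def reference_rhs(a, b, u, p, grid):
    """Independent term-by-term evaluation of the stage equations."""
    lap = grid.laplacian_matrix.toarray() @ a
    u = np.maximum(u, 0.0)
    with np.errstate(divide="ignore", over="ignore"):
        input_term = p.k0 * u**p.q / (1.0 + u**p.q)
        gate = (p.beta * u) ** p.q / (1.0 + (p.beta * u) ** p.q)
        x = gate * np.maximum(a, 0.0)
        fb = p.k1 * x**p.h / (1.0 + x**p.h)
    input_term = np.nan_to_num(input_term, nan=1.0)  # u**q overflow -> term 1
    fb = np.nan_to_num(fb, nan=p.k1)
    da = p.Ds * lap + input_term + fb - p.k2 * a - p.k3 * b * a
    abar = (a * grid.quad_weights).sum() / grid.quad_weights.sum()
    db = p.k4 * (abar - p.k_ss) * b
    return da, db


class TestHill:
    def test_limits_and_midpoint(self):
        assert hill(0.0, 8.0) == 0.0
        assert hill(1.0, 8.0) == pytest.approx(0.5)
        assert hill(1e6, 4.0) == pytest.approx(1.0)
        assert float(hill(0.7, 0.0)) == 0.5  # severed-loop convention

    def test_no_overflow_at_extreme_coefficients(self):
        vals = hill(np.array([0.5, 0.999, 1.001, 2.0]), 1000.0)
        assert np.all(np.isfinite(vals))
        assert vals[0] < 1e-200 and vals[-1] > 1 - 1e-12


class TestGenericRhs:
    def test_matches_independent_term_evaluation(self, rng):
        grid = make_grid("circle", 48, 2.0)
        p = GenericStageParams(k0=2.0, k1=5.0, q=3.0, h=4.0, beta=0.7, Ds=0.1)
        a = rng.uniform(0.1, 2.0, 48)
        b, u = 1.3, rng.uniform(0.0, 2.0, 48)
        state = GenericStageState(Field(a, grid), b)
        da, db = generic_rhs(state, p, u)
        ref_da, ref_db = reference_rhs(a, b, u, p, grid)
        assert np.abs(da.values - ref_da).max() < 1e-12
        assert db == pytest.approx(ref_db, abs=1e-12)

    def test_zero_input_leaves_only_decay_and_diffusion(self, rng):
        grid = make_grid("circle", 32, 2.0)
        p = GenericStageParams(k0=10.0, k1=10.0, q=2.0, h=4.0)
        a = rng.uniform(0.5, 1.5, 32)
        state = GenericStageState(Field(a, grid), 2.0)
        da, _ = generic_rhs(state, p, np.zeros(32))
        expected = p.Ds * (grid.laplacian_matrix @ a) - p.k2 * a - p.k3 * 2.0 * a
        assert np.allclose(da.values, expected)

    def test_saturated_input_production_reaches_term_maxima(self):
        grid = make_grid("circle", 32, 2.0)
        p = GenericStageParams(k0=3.0, k1=7.0, q=2.0, h=2.0, Ds=0.0)
        a = np.full(32, 1e4)
        state = GenericStageState(Field(a, grid), 0.0)
        da, _ = generic_rhs(state, p, np.full(32, 1e6))
        production = da.values + p.k2 * a
        assert np.allclose(production, p.k0 + p.k1, rtol=1e-6)

    def test_nonfinite_state_rejected(self):
        grid = make_grid("circle", 32, 2.0)
        a = np.full(32, np.nan)
        with pytest.raises(ValueError):
            generic_rhs(GenericStageState(Field(a, grid), 1.0),
                        GenericStageParams(), np.ones(32))


class TestPresets:
    @pytest.mark.parametrize("name,k0,k1", [
        ("NPF", 10.0, 0.0), ("PF", 1.0, 10.0),
    ])
    def test_named_rate_constants(self, name, k0, k1):
        p = make_preset(name)
        assert (p.k0, p.k1) == (k0, k1)
        assert p.k2 == p.k3 == p.k4 == 1.0

    def test_feedback_gain_variants(self):
        assert make_preset("low_PF").h == 2.0
        assert make_preset("high_PF").h == 8.0

    def test_slow_variant_scales_rates_tenfold_down(self):
        slow = make_preset("NPF_slow")
        base = make_preset("NPF")
        assert slow.k0 == pytest.approx(base.k0 * 0.1)
        assert slow.k4 == pytest.approx(0.1)
        assert slow.Ds == base.Ds
        assert slow.speed_factor == pytest.approx(0.1)

    def test_cascade_wiring_and_filter_first_stage(self):
        casc = make_preset("NPF+PF")
        assert isinstance(casc, CascadeSpec) and casc.n_stages == 2
        assert casc.stages[0].k0 == 10.0 and casc.stages[0].q == 2.0
        assert casc.stages[1].k1 == 10.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_preset("NPFX")


class TestScaleSpeed:
    def test_identity_and_inverse(self):
        p = make_preset("PF")
        assert scale_speed(p, 1.0) == p
        roundtrip = scale_speed(scale_speed(p, 10.0), 0.1)
        for name in ("k0", "k1", "k2", "k3", "k4"):
            assert getattr(roundtrip, name) == pytest.approx(getattr(p, name))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_speed(make_preset("NPF"), 0.0)

    def test_time_rescaling_with_coscaled_diffusion(self):
        # with Ds co-scaled, a 4x faster model reaches in t/4 the same
        # state the base model reaches at t (pure time rescaling)
        from dataclasses import replace
        grid = make_grid("axisymmetric_sphere", 64, 2.0)
        grad = GradientSpec(L_mid=1.0, L_slp=0.1)
        base = make_preset("NPF")
        fast = replace(scale_speed(base, 4.0), Ds=base.Ds * 4.0)
        proc = InputProcess(grad, NoiseSpec(sigma=0.0), grid)
        t1 = simulate_generic(base, proc, t_end=8.0, burn_in=0.0)
        t2 = simulate_generic(fast, proc, t_end=2.0, burn_in=0.0)
        assert t1.species["af1"][-1] == pytest.approx(
            t2.species["af1"][-1], rel=1e-3)


class TestSimulateGeneric:
    def test_uniform_input_adapts_to_k_ss(self):
        grid = make_grid("axisymmetric_sphere", 64, 2.0)
        proc = InputProcess(GradientSpec(L_mid=1.0), NoiseSpec(sigma=0.0), grid)
        traj = simulate_generic(make_preset("NPF"), proc, t_end=1.0,
                                burn_in=60.0)
        a = traj.species["a1"][-1]
        assert np.allclose(a, 1.0, atol=0.01)           # uniform at k_ss
        assert traj.species["abar1"][-1] == pytest.approx(1.0, abs=0.01)

    def test_adaptation_across_two_decades_of_input(self):
        # steady-state surface average returns to k_ss for uniform inputs
        # spanning 100x (all above the ultrasensitive sensing threshold,
        # below which there is no production for the loop to regulate;
        # the bistable PF regime adapts only once its feedback is ignited,
        # so the invariant is checked on the ultrasensitive module)
        grid = make_grid("axisymmetric_sphere", 48, 2.0)
        for L_mid in (1.0, 10.0, 100.0):
            proc = InputProcess(GradientSpec(L_mid=L_mid), NoiseSpec(sigma=0.0),
                                grid)
            traj = simulate_generic(make_preset("NPF"), proc, t_end=1.0,
                                    burn_in=300.0)
            assert traj.species["abar1"][-1] == pytest.approx(1.0, rel=0.01)

    def test_batched_run_matches_single_seed(self):
        grid = make_grid("axisymmetric_sphere", 48, 2.0)
        grad, noise = GradientSpec(1.0, 0.1), NoiseSpec(sigma=0.5)
        batch = BatchedInputProcess(grad, noise, grid, seeds=[3, 4])
        single = InputProcess(grad, NoiseSpec(sigma=0.5, seed=3), grid)
        tb = simulate_generic(make_preset("NPF"), batch, t_end=2.0, burn_in=5.0)
        ts = simulate_generic(make_preset("NPF"), single, t_end=2.0, burn_in=5.0)
        assert np.allclose(tb.species["af1"][:, 0], ts.species["af1"])

    def test_imex_matches_explicit_euler_trajectory(self):
        grid = make_grid("axisymmetric_sphere", 48, 2.0)
        proc = InputProcess(GradientSpec(1.0, 0.1), NoiseSpec(sigma=0.0), grid)
        imex = simulate_generic(make_preset("NPF"), proc, t_end=1.0,
                                burn_in=0.0, dt=0.01, scheme="imex")
        euler = simulate_generic(make_preset("NPF"), proc, t_end=1.0,
                                 burn_in=0.0, dt=0.0001, scheme="euler",
                                 record_every=100)
        assert imex.species["af1"][-1] == pytest.approx(
            euler.species["af1"][-1], rel=1e-3)
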