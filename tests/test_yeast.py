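"""Yeast mechanistic model: equations, conservation, mutants, speed scaling."""

import numpy as np
import pytest

from polarsim.geometry import make_grid, surface_average
from polarsim.inputs import GradientSpec, InputProcess, NoiseSpec
from polarsim.yeast import (
    MEMBRANE_SPECIES,
    HillSpec,
    YeastParams,
    YeastState,
    apply_mutant,
    initial_state,
    scale_gprotein_speed,
    simulate_yeast,
    yeast_rhs,
)


def reference_rhs(f, cla4a, p, L, grid):
    """Independent, loop-based evaluation of all eleven equations."""
    n = grid.n_points
    w = grid.quad_weights / grid.quad_weights.sum()
    lap = grid.laplacian_matrix.toarray()
    c24c = 1.0 - (w * f["C24m"]).sum() / p.C24_pool
    b1c = 1.0 - (w * f["B1m"]).sum() / p.B1_pool
    c42a_avg = (w * f["C42a"]).sum()
    d = {k: np.zeros(n) for k in MEMBRANE_SPECIES}
    for i in range(n):
        ps = 1.0 if p.bni1_delta else (
            f["C42a"][i] / c42a_avg if c42a_avg > 0 else 1.0)
        bind = p.kRL * L[i] * f["R"][i]
        unb = p.kRLm * f["RL"][i]
        gact = p.kGa * f["RL"][i] * f["G"][i]
        gre = p.kG1 * f["Gd"][i] * f["Gbg"][i]
        rec = (p.k24cm0 * p.f_Gbg(f["Gbg"][i] / p.G_total)
               + p.k24cm1 * p.f_Bem1(f["B1m"][i])) * c24c
        act = p.k42a * f["C24m"][i] * f["C42"][i]
        d["R"][i] = -bind + unb - p.kRd0 * f["R"][i] + ps * p.kRs
        d["RL"][i] = bind - unb - p.kRd1 * f["RL"][i]
        d["G"][i] = -gact + gre
        d["Ga"][i] = gact - p.kGd * f["Ga"][i]
        d["Gbg"][i] = gact - gre
        d["Gd"][i] = p.kGd * f["Ga"][i] - gre
        d["C24m"][i] = (rec - p.k24mc * f["C24m"][i]
                        - p.k24d * cla4a * f["C24m"][i])
        d["C42"][i] = -act + p.k42d * f["C42a"][i]
        d["C42a"][i] = act - p.k42d * f["C42a"][i]
        d["B1m"][i] = p.kB1cm * f["C42a"][i] * b1c - p.kB1mc * f["B1m"][i]
    for k in d:
        d[k] = d[k] + p.D * (lap @ f[k])
    d_cla4 = p.kCla4a * p.f_Cla4(c42a_avg) - p.kCla4d * cla4a
    return d, d_cla4


def random_state(p, grid, rng):
    f = {k: rng.uniform(0.5, 5.0, grid.n_points) for k in MEMBRANE_SPECIES}
    f["R"] = rng.uniform(10, 100, grid.n_points)
    f["G"] = rng.uniform(10, 100, grid.n_points)
    return YeastState(f, 1.7, grid, p)


class TestYeastRhs:
    def test_matches_independent_term_evaluation(self, rng):
        grid = make_grid("circle", 24, 2.0)
        p = YeastParams()
        st = random_state(p, grid, rng)
        L = rng.uniform(0, 20, grid.n_points)
        d, d_cla4 = yeast_rhs(st, p, L)
        ref, ref_cla4 = reference_rhs(st.fields, st.Cla4a, p, L, grid)
        for k in MEMBRANE_SPECIES:
            assert np.abs(d[k] - ref[k]).max() < 1e-12, k
        assert d_cla4 == pytest.approx(ref_cla4, abs=1e-12)

    def test_conserved_totals_have_zero_net_rate(self, rng):
        grid = make_grid("circle", 24, 2.0)
        p = YeastParams()
        st = random_state(p, grid, rng)
        d, _ = yeast_rhs(st, p, rng.uniform(0, 20, grid.n_points))
        w = grid.quad_weights
        for names in (("G", "Ga", "Gd"), ("G", "Gbg"), ("C42", "C42a")):
            total_rate = sum((d[k] * w).sum() for k in names)
            scale = max(abs((st.fields[k] * w).sum()) for k in names)
            assert abs(total_rate) < 1e-10 * scale

    def test_no_ligand_leaves_only_receptor_turnover(self):
        grid = make_grid("circle", 16, 2.0)
        p = YeastParams()
        st = initial_state(p, grid)
        d, _ = yeast_rhs(st, p, np.zeros(16))
        # R balanced at its synthesis/removal steady state; all else quiet
        assert np.allclose(d["R"], 0.0, atol=1e-12)
        for k in ("RL", "Ga", "Gbg", "Gd", "C24m", "C42a", "B1m"):
            assert np.allclose(d[k], 0.0, atol=1e-12), k

    def test_nonfinite_state_rejected(self, rng):
        grid = make_grid("circle", 16, 2.0)
        p = YeastParams()
        st = random_state(p, grid, rng)
        st.fields["G"][0] = np.nan
        with pytest.raises(ValueError):
            yeast_rhs(st, p, np.ones(16))


class TestMutants:
    def test_wild_type_is_identity(self):
        p = YeastParams()
        assert apply_mutant(p, "wild_type") is p

    def test_bem1_removes_b1m_dependence(self, rng):
        grid = make_grid("circle", 16, 2.0)
        p = apply_mutant(YeastParams(), "bem1_delta")
        assert p.bem1_delta
        st = random_state(p, grid, rng)
        d1, _ = yeast_rhs(st, p, np.full(16, 10.0))
        st.fields["B1m"] = st.fields["B1m"] * 3.0  # perturb the scaffold
        d2, _ = yeast_rhs(st, p, np.full(16, 10.0))
        assert np.allclose(d1["C24m"], d2["C24m"])

    def test_bem1_soft_variant_keeps_constant_half_recruitment(self, rng):
        p = apply_mutant(YeastParams(), "bem1_delta", hard_zero=False)
        assert p.f_Bem1.n == 0
        assert float(p.f_Bem1(0.1)) == 0.5 == float(p.f_Bem1(50.0))

    def test_bni1_makes_synthesis_isotropic(self, rng):
        grid = make_grid("circle", 16, 2.0)
        wt = YeastParams()
        mut = apply_mutant(wt, "bni1_delta")
        st = random_state(wt, grid, rng)
        d_wt, _ = yeast_rhs(st, wt, np.full(16, 10.0))
        st_mut = YeastState(st.fields, st.Cla4a, grid, mut)
        d_mut, _ = yeast_rhs(st_mut, mut, np.full(16, 10.0))
        # mutant synthesis is uniform kRs; wild type modulates it by p_s
        diff = d_wt["R"] - d_mut["R"]
        ps = st.fields["C42a"] / surface_average(st.fields["C42a"], grid)
        assert np.allclose(diff, (ps - 1.0) * wt.kRs)

    def test_unknown_mutant_rejected(self):
        with pytest.raises(ValueError):
            apply_mutant(YeastParams(), "cdc42_delta")


class TestGproteinSpeedScaling:
    def test_identity(self):
        p = YeastParams()
        assert scale_gprotein_speed(p, 1.0) == p

    def test_scales_only_stage_one(self):
        p = YeastParams()
        fast = scale_gprotein_speed(p, 10.0)
        for name in ("kRL", "kRLm", "kRd0", "kRd1", "kRs", "kGa", "kGd", "kG1"):
            assert getattr(fast, name) == pytest.approx(10 * getattr(p, name))
        for name in ("k24cm0", "k42a", "kB1cm", "kCla4a", "D"):
            assert getattr(fast, name) == getattr(p, name)
        assert fast.gprotein_speed_factor == 10.0

    def test_factors_compose_multiplicatively(self):
        p = YeastParams()
        twice = scale_gprotein_speed(scale_gprotein_speed(p, 0.1), 0.1)
        assert twice.kGd == pytest.approx(p.kGd * 0.01)
        assert twice.gprotein_speed_factor == pytest.approx(0.01)


class TestSimulateYeast:
    def test_conservation_drift_below_tolerance(self):
        # relative drift of the conserved totals < 1e-6 per simulated minute
        grid = make_grid("circle", 32, 2.0)
        p = YeastParams()
        proc = InputProcess(GradientSpec(10.0, 0.01),
                            NoiseSpec(sigma=1.0, seed=0), grid)
        traj = simulate_yeast(p, proc, t_end=60.0, burn_in=10.0,
                              record_every=100)
        state0 = initial_state(p, grid)
        start = state0.conservation_totals()
        end = traj.metadata["final_state"].conservation_totals()
        for key in ("Galpha", "Gbetagamma", "Cdc42"):
            drift = abs(end[key] - start[key]) / start[key]
            assert drift < 1e-6 * (70.0 / 60.0), key

    def test_receptor_count_at_rest(self):
        # ~10,000 receptors evenly distributed on a radius-2um sphere
        grid = make_grid("circle", 32, 2.0)
        p = YeastParams()
        proc = InputProcess(GradientSpec(0.0), NoiseSpec(sigma=0.0), grid)
        traj = simulate_yeast(p, proc, t_end=1.0, burn_in=500.0,
                              record_every=100)
        st = traj.metadata["final_state"]
        density = st.fields["R"].mean() + st.fields["RL"].mean()
        count = density * 16 * np.pi
        assert count == pytest.approx(10000, rel=0.05)

    def test_same_seed_reproducible(self):
        grid = make_grid("circle", 24, 2.0)
        p = YeastParams()

        def run():
            proc = InputProcess(GradientSpec(10.0), NoiseSpec(sigma=3.0, seed=9),
                                grid)
            return simulate_yeast(p, proc, t_end=5.0, burn_in=1.0,
                                  record_every=100)

        a, b = run(), run()
        assert np.array_equal(a.species["C42a"][-1], b.species["C42a"][-1])

    def test_metadata_records_conditions(self):
        grid = make_grid("circle", 16, 2.0)
        p = scale_gprotein_speed(YeastParams(), 10.0)
        proc = InputProcess(GradientSpec(10.0, 0.01), NoiseSpec(sigma=1.0), grid)
        traj = simulate_yeast(p, proc, t_end=1.0, burn_in=0.0)
        md = traj.metadata
        assert md["gprotein_speed_factor"] == 10.0
        assert md["mutant"] == "wild_type"
        assert md["sigma"] == 1.0 and md["L_slp"] == 0.01
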