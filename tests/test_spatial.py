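import numpy as np
import pytest

from plantclock import (
    ClockState,
    CouplingConfig,
    LightProtocol,
    RegionNoiseSpec,
    build_template,
    coupled_rhs,
    run_protocol,
    simulate_cell,
)
from plantclock.model import GENE_INDEX, NSTATE, rhs_vectorized
from plantclock.parameters import DEFAULT_PARAMS
from plantclock.template import SeedlingTemplate, TemplateGeometry


def toy_lattice(n=3, region="root", l_sens=1.0):
    """A small square lattice built directly (no seedling anatomy)."""
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    k = n * n
    return SeedlingTemplate(
        col=cols.ravel(), row=rows.ravel(),
        region=np.full(k, region), L_sens=np.full(k, l_sens),
        tau=np.ones(k),
    )


class TestCoupledRhs:
    def test_identical_states_make_coupling_vanish(self, rng):
        """Synchrony is invariant: cbar = c, so J contributes nothing."""
        tpl = toy_lattice(4)
        proto = LightProtocol("LL", entrain_days=1)
        y = np.tile(rng.uniform(0.1, 2.0, NSTATE), (tpl.n_cells, 1))
        d0 = coupled_rhs(y, 3.0, tpl, CouplingConfig(J_local=0.0), proto)
        d2 = coupled_rhs(y, 3.0, tpl, CouplingConfig(J_local=2.0), proto)
        np.testing.assert_allclose(d0, d2, atol=1e-14)

    @pytest.mark.parametrize("species,form", [("CL", "mRNA"), ("EL", "protein")])
    def test_toy_lattice_matches_explicit_neighbor_loop(self, rng, species, form):
        """Oracle: per-cell coupling term assembled by an explicit loop."""
        tpl = toy_lattice(3)
        tpl.tau = rng.uniform(0.8, 1.2, tpl.n_cells)
        proto = LightProtocol("LD_ideal", entrain_days=1)
        coup = CouplingConfig(J_local=2.0, species=species, form=form)
        y = rng.uniform(0.05, 2.0, (tpl.n_cells, NSTATE))
        got = coupled_rhs(y, 5.0, tpl, coup, proto)

        ci = coup.coupled_index
        nbrs = tpl.neighbor_lists("4")
        for i in range(tpl.n_cells):
            li = proto.light_at(i, 5.0)
            base = rhs_vectorized(y[i], li.L, li.D, tpl.L_sens[i], DEFAULT_PARAMS)
            cbar = np.mean([y[j, ci] for j in nbrs[i]])
            base[ci] += coup.J_local * (cbar - y[i, ci])
            np.testing.assert_allclose(got[i], base / tpl.tau[i], rtol=1e-12)

    def test_corner_cells_average_over_existing_neighbors_only(self):
        tpl = toy_lattice(3)
        nbrs = tpl.neighbor_lists("4")
        corner = 0
        assert len(nbrs[corner]) == 2

    def test_global_coupling_contributions_sum_to_zero(self, rng):
        tpl = toy_lattice(4)
        A = tpl.averaging_matrix("global")
        c = rng.uniform(0.0, 2.0, tpl.n_cells)
        assert np.sum(A.dot(c) - c) == pytest.approx(0.0, abs=1e-12)

    def test_long_distance_term_targets_root_tip_only(self, rng):
        geo = TemplateGeometry(cotyledon_w=3, cotyledon_h=4, hypocotyl_w=2,
                               hypocotyl_h=5, root_h=6, root_tip_h=3)
        tpl = build_template(geo)
        proto = LightProtocol("LL", entrain_days=1)
        y = rng.uniform(0.1, 1.5, (tpl.n_cells, NSTATE))
        d0 = coupled_rhs(y, 1.0, tpl, CouplingConfig(J_long=0.0), proto)
        d1 = coupled_rhs(y, 1.0, tpl, CouplingConfig(J_long=1.5), proto)
        diff = d1 - d0
        elp = GENE_INDEX["EL"][1]
        tip = tpl.root_tip_cells
        hypo = tpl.hypocotyl_cells
        expected = 1.5 * (y[hypo, elp].mean() - y[tip, elp])
        np.testing.assert_allclose(diff[tip, elp], expected, rtol=1e-12)
        diff[tip, elp] = 0.0
        np.testing.assert_allclose(diff, 0.0, atol=1e-14)

    def test_unknown_coupled_species_rejected(self):
        with pytest.raises(ValueError):
            CouplingConfig(species="GI")


class TestRunProtocol:
    def test_decoupled_homogeneous_lattice_equals_single_cell(self):
        """J = 0, tau = 1, uniform L_sens: every cell is the single-cell run."""
        tpl = toy_lattice(3, l_sens=1.0)
        proto = LightProtocol("LD_ideal", entrain_days=2)
        res = run_protocol(
            tpl, CouplingConfig(J_local=0.0), proto,
            noise_spec=RegionNoiseSpec.zero(), growth=False, dt_max=0.05,
        )
        X = res.series("cCLm")
        # all cells identical to each other (exactly)
        assert np.max(np.abs(X - X[:, [0]])) < 1e-12
        # identical to the ensemble integrator at the same step cap
        from plantclock.fitting import Phase, simulate_conditions

        _, Y, _ = simulate_conditions(DEFAULT_PARAMS, [Phase("LD", 2)],
                                      dt_max=0.05)
        assert np.max(np.abs(Y[:, 0, 0] - X[:, 0])) < 1e-8
        # and agrees with the adaptive single-cell solution
        traj = simulate_cell(DEFAULT_PARAMS, proto)
        assert np.max(np.abs(traj.variable("cCLm") - X[:, 0])) < 1e-4

    def test_same_seed_and_config_reproduce_bit_identically(self, small_template):
        proto = LightProtocol("LD_noisy", entrain_days=2, lam=0.25, seed=44)
        kwargs = dict(record=("cP97m",), growth=True)
        a = run_protocol(small_template, CouplingConfig(J_local=1.0), proto,
                         seed=9, **kwargs)
        b = run_protocol(small_template, CouplingConfig(J_local=1.0), proto,
                         seed=9, **kwargs)
        np.testing.assert_array_equal(a.series("cP97m"), b.series("cP97m"))
        np.testing.assert_array_equal(a.template.tau, b.template.tau)

    def test_growth_extends_state_and_marks_unborn_cells(self, small_template):
        proto = LightProtocol("LD_ideal", entrain_days=3)
        res = run_protocol(small_template, CouplingConfig(), proto, seed=2,
                           record=("cCLm",))
        width = small_template.geometry.hypocotyl_w
        assert res.n_cells == small_template.n_cells + 2 * width
        X = res.series("cCLm")
        born_day2 = res.growth_log[1][1].new_cell_ids
        assert np.isnan(X[0, born_day2]).all()
        assert np.isfinite(X[-1, born_day2]).all()
        # new cells start from the adjacent interior row's state
        ev = res.growth_log[0][1]
        t_birth = np.searchsorted(res.t, 24.0) + 1
        assert np.isfinite(X[t_birth, ev.new_cell_ids]).all()

    def test_matched_tau_fields_across_protocols(self, small_template):
        """The run seed pins the tau field regardless of the light protocol."""
        ideal = LightProtocol("LD_ideal", entrain_days=2)
        noisy = LightProtocol("LD_noisy", entrain_days=2, lam=0.0, seed=77)
        a = run_protocol(small_template, CouplingConfig(), ideal, seed=5,
                         record=("cCLm",))
        b = run_protocol(small_template, CouplingConfig(), noisy, seed=5,
                         record=("cCLm",))
        np.testing.assert_array_equal(a.template.tau, b.template.tau)

    def test_trajectories_nonnegative(self, small_template):
        proto = LightProtocol("LD_noisy", entrain_days=2, lam=0.5, seed=3)
        res = run_protocol(small_template, CouplingConfig(J_local=2.0), proto,
                           seed=1)
        for var, X in res.data.items():
            assert np.nanmin(X) >= 0.0, var
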