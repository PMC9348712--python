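"""Scaling, recruitment, per-step workflow, determinism, coarse graining."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spqsp.coupling import (CouplingState, coarse_grain_rates,
                            inverse_scale_abm_to_qsp, place_entry_points,
                            recruitment_probability, recruitment_weight,
                            scale_qsp_to_abm)
from spqsp.agents import RuleParams
from spqsp.lattice import (CSC, MDSC, PC, SC, TCYT, TEFF, TREG, GridSpec)
from spqsp.scenarios import (get_scenario, build_world_for, table4_scenarios,
                             build_front_world)
from tests.conftest import make_world


class TestScaling:
    def test_gamma_one_identity(self):
        assert scale_qsp_to_abm(1234.0, 1.0) == 1234

    def test_floor_arithmetic(self):
        assert scale_qsp_to_abm(1.5e5, 5e4) == 3
        assert scale_qsp_to_abm(4.9e4, 5e4) == 0

    @given(count=st.floats(0, 1e12), gamma=st.floats(1, 1e6))
    @settings(derandomize=True, max_examples=60)
    def test_floor_bounds(self, count, gamma):
        n = scale_qsp_to_abm(count, gamma)
        assert n * gamma <= count + 1e-3
        assert (n + 1) * gamma > count - 1e-3 or n == 0


class TestInverseScaling:
    def test_empty_census(self):
        out = inverse_scale_abm_to_qsp({}, 5e4)
        assert all(v == 0.0 for v in out.values())

    def test_cancer_pool(self):
        out = inverse_scale_abm_to_qsp({CSC: 2, PC: 3, SC: 1}, 10.0)
        assert out["C"] == 60.0

    def test_effector_and_cytotoxic_pool(self):
        out = inverse_scale_abm_to_qsp({TEFF: 4, TCYT: 1}, 5e4)
        assert out["T1"] == 2.5e5


class TestRecruitmentProbability:
    def test_zero_propensity(self):
        assert recruitment_probability(0.0, 1.0, 1.0) == 0.0

    def test_ln2(self):
        assert recruitment_probability(math.log(2.0), 2.0, 2.0) == pytest.approx(0.5)

    def test_first_order_expansion(self):
        p = recruitment_probability(0.01, 1.0, 1.0)
        assert p == pytest.approx(0.00995, rel=1e-3)
        assert abs(p - 0.01) / 0.01 < 0.01


class TestEntryPoints:
    def test_full_fraction_covers_grid(self, rng):
        grid = GridSpec(6, 6, 2)
        f = place_entry_points(grid, 1.0, rng)
        assert len(f.entry_voxels) == grid.n_voxels
        assert len(np.unique(f.entry_voxels)) == grid.n_voxels

    def test_ten_percent_count(self, rng):
        grid = GridSpec(20, 20, 20)
        f = place_entry_points(grid, 0.1, rng)
        assert len(f.entry_voxels) == 800
        assert len(np.unique(f.entry_voxels)) == 800   # one point per voxel

    def test_out_of_range_fraction(self, rng):
        with pytest.raises(ValueError):
            place_entry_points(GridSpec(4, 4, 4), 0.0, rng)


class TestRecruitmentWeight:
    def test_uniform_zero_density_equal_weights(self):
        w = recruitment_weight(np.zeros(50))
        assert np.all(w == w[0])

    def test_peak_at_mid_band(self):
        band = (0.1, 0.5)
        w_mid = recruitment_weight(0.3, band=band, w0=0.1, peak=1.0)
        assert w_mid == pytest.approx(1.0)
        assert recruitment_weight(0.3, band=band) > recruitment_weight(0.12, band=band)

    def test_core_gets_floor(self):
        assert recruitment_weight(0.98, w0=0.1, peak=1.0) == pytest.approx(0.1)
        assert recruitment_weight(0.0, w0=0.1, peak=1.0) == pytest.approx(0.1)


class TestFluxMatching:
    def test_gamma_scaled_influx_matches_qsp_flux(self):
        """Homogeneous weights, constant flux F over 500 steps: the
        γ-scaled recruitment count stays within 3 binomial SE of F·t."""
        gamma, tau = 4.0, 0.25
        w = make_world(grid=GridSpec(10, 10, 10), gamma=gamma, tau=tau,
                       seed=42, rv=0.5)
        F = 40.0   # cells/day
        w.qsp_params = w.qsp_params.with_overrides(
            k_T1_rec=1.0, K_presence=0.0, k_MDSC_base=0.0)
        w.qsp_state.T1_central = F
        w.qsp_state.C = 100.0   # gate open
        n_steps = 500
        for _ in range(n_steps):
            w.recruit_cells(tau)
        expected_agents = F * tau * n_steps / gamma
        got = w.recruited_totals[TEFF]
        se = math.sqrt(expected_agents)
        assert abs(got - expected_agents) < 3.0 * se

    def test_mdsc_recruitment_monotone_in_ccl2(self):
        counts = []
        for ccl2 in (0.0, 1.0, 10.0):
            w = make_world(grid=GridSpec(10, 10, 10), seed=77, rv=0.5)
            w.qsp_params = w.qsp_params.with_overrides(
                k_MDSC_base=5.0, k_MDSC_ccl2=100.0, K_presence=0.0)
            w.qsp_state.C = 10.0
            w.qsp_state.CCL2 = ccl2
            for _ in range(300):
                w.recruit_cells(0.25)
                for a in list(w.agents.values()):   # keep entry voxels free
                    w.remove_agent(a)
            counts.append(w.recruited_totals[MDSC])
        assert counts[0] < counts[1] < counts[2]


class TestStepWorkflow:
    def test_all_rates_zero_leaves_world_unchanged(self):
        rules = RuleParams(r_st=0.0, r_p=0.0, mu=0.0, u_st=0.0, u_p=0.0,
                           u_T=0.0, u_mdsc=0.0, kC_T1=0.0, kT1=0.0,
                           kTreg=0.0, d_T=0.0, d_Treg=0.0, d_MDSC=0.0,
                           k_T0_exp=0.0)
        w = make_world(rules=rules, seed=5)
        w.add_agent(PC, (3, 3, 3))
        w.add_agent(TEFF, (8, 8, 8))
        before = {a.id: (a.kind, a.position) for a in w.agents.values()}
        t0 = w.t
        for _ in range(10):
            w.step()
        after = {a.id: (a.kind, a.position) for a in w.agents.values()}
        assert after == before
        assert w.t == pytest.approx(t0 + 10 * 0.25)

    def test_inverse_scaling_identity_every_step(self):
        """After each step the QSP tumor counts equal γ x census exactly
        (integer equality before the ODE advance touches other species)."""
        sc = get_scenario("wellmixed")
        w = build_world_for(sc, seed=9)
        for _ in range(20):
            w.step()
            counts = inverse_scale_abm_to_qsp(w.census, w.coupling.gamma)
            # C may have been integrated .. no: tumor species are frozen
            assert w.qsp_state.C == counts["C"]
            assert w.qsp_state.T1 == counts["T1"]
            assert w.qsp_state.T0 == counts["T0"]
            assert w.qsp_state.MDSC == counts["MDSC"]
            assert w.qsp_state.Texh == counts["Texh"]

    def test_fixed_seed_bitwise_reproducible(self):
        sc = get_scenario("wellmixed")
        runs = []
        for _ in range(2):
            w = build_world_for(sc, seed=123)
            for _ in range(12):
                w.step()
            runs.append(w.timeseries())
        assert runs[0].equals(runs[1])

    def test_occupancy_audit_over_fixture_run(self):
        sc = table4_scenarios()["medium"]
        w = build_front_world(sc, seed=4)
        for _ in range(16):
            w.step(audit=True)   # audit raises on any violation


class TestCoarseGraining:
    def test_gamma_one_identity(self):
        p = RuleParams()
        assert coarse_grain_rates(p, 1.0) == p

    def test_gamma_eight_halves_migration(self):
        p = RuleParams(u_st=4.0, u_p=6.0, u_T=10.0, u_mdsc=2.0)
        q = coarse_grain_rates(p, 8.0)
        assert q.u_st == pytest.approx(2.0)
        assert q.u_p == pytest.approx(3.0)
        assert q.u_T == pytest.approx(5.0)
        assert q.r_p == p.r_p            # reaction rates untouched
        assert q.kC_T1 == p.kC_T1

    def test_paper_gamma_factor(self):
        q = coarse_grain_rates(RuleParams(u_p=1.0), 5e4)
        assert q.u_p == pytest.approx(5e4 ** (-1 / 3), rel=1e-12)
        assert q.u_p == pytest.approx(0.02714, abs=2e-5)


class TestInitialization:
    def test_single_cell_policy(self):
        sc = get_scenario("fig3_a")
        w = build_world_for(sc, seed=0)
        assert w.census[CSC] == 1
        assert w.qsp_state.C == sc.coupling.gamma

    def test_diameter_condition_seeds_scaled_counts(self):
        w = make_world(grid=GridSpec(24, 24, 24), gamma=50.0, tau=0.5)
        w.coupling.initialized = False
        w.qsp_params = w.qsp_params.with_overrides(kC1_growth=0.5, C_max=1e9)
        w.qsp_state.C = 1e4
        w.initialize_coupling(policy="diameter_condition", d0_mm=0.8,
                              seed_kwargs={"profile": "sphere",
                                           "sigma_mm": 0.15})
        from spqsp.qsp import tumor_volume
        _, diam = tumor_volume(w.qsp_state, w.qsp_params.cell_volume)
        assert diam >= 0.79   # flooring C/gamma may shave a sliver
        n_cancer = w.census[CSC] + w.census[PC] + w.census[SC]
        assert n_cancer == int(w.qsp_state.C // 50.0)

    def test_unreachable_diameter_raises(self):
        w = make_world()
        w.coupling.initialized = False
        w.qsp_state.C = 10.0   # zero growth in quiet params
        with pytest.raises(RuntimeError, match="unreachable"):
            w.initialize_coupling(policy="diameter_condition", d0_mm=50.0,
                                  max_time=2.0)
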