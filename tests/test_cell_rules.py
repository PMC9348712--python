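"""Agent state machines against their closed-form and branching oracles."""

import math

import numpy as np
import pytest

from spqsp.agents import (MediatorEnvironment, RuleParams, event_probability,
                          exhaustion_probability, generic_decay,
                          killing_probability, sc_death, tcell_activation,
                          treg_expansion_probability)
from spqsp.lattice import CSC, PC, SC, TCYT, TEFF, GridSpec
from spqsp.agents import CellAgent
from tests.conftest import make_world


def grow_only_world(rules, n=20, seed=0, tau=0.25):
    w = make_world(grid=GridSpec(n, n, n), rules=rules, seed=seed, tau=tau)
    w.add_agent(CSC if rules.r_st > 0 else PC,
                (n // 2, n // 2, n // 2))
    return w


class TestEventProbability:
    def test_zero_rate(self):
        assert event_probability(0.0, 1.0) == 0.0

    def test_ln2_half(self):
        assert event_probability(math.log(2.0), 1.0) == pytest.approx(0.5)

    def test_small_rate_first_order(self):
        assert event_probability(0.01, 1.0) == pytest.approx(0.00995, abs=1e-5)


class TestCSCDivision:
    def test_pure_asymmetric_keeps_single_csc(self):
        rules = RuleParams(k=1.0, r_st=2.0, r_p=0.0, mu=0.0, u_st=0.0, u_p=0.0)
        w = grow_only_world(rules, seed=3)
        w.run(10.0)
        assert w.census[CSC] == 1
        assert w.census[PC] > 5

    def test_symmetric_division_is_yule_process(self):
        """k=0: CSC count is a Yule process; the replicate mean must match
        exp(r_st * t) within 3 standard errors (branching oracle)."""
        r_st, t = 0.3, 6.0
        rules = RuleParams(k=0.0, r_st=r_st, r_p=0.0, mu=0.0,
                           u_st=5.0, u_p=0.0, u_T=0.0)
        counts = []
        for rep in range(200):
            w = grow_only_world(rules, n=16, seed=100 + rep, tau=0.1)
            w.run(t)
            counts.append(w.census[CSC])
        counts = np.asarray(counts, dtype=float)
        mean = counts.mean()
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(mean - math.exp(r_st * t)) < 3.0 * se


class TestPCDivision:
    @pytest.mark.parametrize("d_max,expected_sc", [(1, 2), (2, 4), (3, 8)])
    def test_terminal_clone_size_is_2_pow_dmax(self, d_max, expected_sc):
        """One founder PC, no death, open space: the division tree is the
        full binary tree of depth d_max (enumeration oracle: both daughters
        inherit the incremented count), so exactly 2^d_max SCs remain."""
        rules = RuleParams(k=0.0, r_st=0.0, r_p=3.0, d_max=d_max, mu=0.0,
                           u_st=0.0, u_p=5.0, u_T=0.0)
        w = grow_only_world(rules, n=14, seed=7 + d_max)
        for _ in range(400):
            w.step()
            if w.census[PC] == 0:
                break
        assert w.census[PC] == 0
        assert w.census[SC] == expected_sc

    def test_division_budget_never_exceeded(self):
        rules = RuleParams(k=0.6, r_st=1.0, r_p=2.0, d_max=4, mu=0.0,
                           u_st=2.0, u_p=2.0, u_T=0.0)
        w = grow_only_world(rules, n=16, seed=11)
        w.run(6.0)
        for a in w.agents.values():
            if a.kind == PC:
                assert a.divisions_done < 4
            if a.kind == SC:
                assert a.divisions_done == 4   # SCs arise exactly at d_max


class TestDeath:
    def test_zero_rate_immortal(self, rng):
        cell = CellAgent(0, SC, (0, 0, 0))
        assert not any(sc_death(cell, 0.0, 1.0, rng) for _ in range(200))

    def test_ln2_step_probability(self):
        assert event_probability(math.log(2.0), 1.0) == pytest.approx(0.5)

    def test_population_half_life(self, rng):
        """1e4 senescent cells decaying at mu: empirical half-life within
        5% of ln2/mu at a fixed seed (exponential-decay oracle)."""
        mu, dt = 0.4, 0.05
        n = 10_000
        p = event_probability(mu, dt)
        alive = n
        t = 0.0
        while alive > n // 2:
            alive -= rng.binomial(alive, p)
            t += dt
        assert t == pytest.approx(math.log(2.0) / mu, rel=0.05)


class TestActivation:
    def test_no_cancer_in_reach_stays_effector(self):
        assert tcell_activation(CellAgent(0, TEFF, (0, 0, 0)), 0) == TEFF

    def test_adjacent_cancer_activates(self):
        assert tcell_activation(CellAgent(0, TEFF, (0, 0, 0)), 1) == TCYT

    def test_chebyshev_two_is_out_of_reach(self):
        """A cancer cell two voxels away is outside the Moore neighborhood
        sum, so the count seen by the effector is zero."""
        w = make_world(grid=GridSpec(7, 7, 7))
        w.add_agent(PC, (0, 0, 0))
        w.add_agent(TEFF, (2, 0, 0))
        from spqsp.coupling import _box_sum
        nbh = _box_sum(w.cancer_count_grid()).ravel()
        assert nbh[w.grid.flat((2, 0, 0))] == 0
        assert nbh[w.grid.flat((1, 0, 0))] == 1


class TestKilling:
    def test_no_cytotoxic_no_kill(self):
        p = killing_probability(0, MediatorEnvironment(), RuleParams(), 1.0)
        assert p == 0.0

    def test_ln2_closed_form(self):
        rules = RuleParams(kC_T1=math.log(2.0), K_PD1=1e12)  # f_PD1 ~ 1
        env = MediatorEnvironment()   # NO = ArgI = 0 -> f = 1
        assert killing_probability(1, env, rules, 1.0) == pytest.approx(0.5, rel=1e-9)

    def test_mediators_suppress_and_drug_restores(self):
        rules = RuleParams(kC_T1=1.0)
        base = killing_probability(1, MediatorEnvironment(), rules, 1.0)
        suppressed = killing_probability(
            1, MediatorEnvironment(NO=5.0, ArgI=100.0), rules, 1.0)
        blocked = killing_probability(
            1, MediatorEnvironment(pd1_occupancy=1.0), rules, 1.0)
        assert suppressed < base < blocked


class TestExhaustion:
    def test_zero_rates_never_exhaust(self):
        rules = RuleParams(kT1=0.0, kTreg=0.0)
        assert exhaustion_probability(3, 5, MediatorEnvironment(), rules, 1.0) == 0.0

    def test_full_blockade_no_tregs_is_safe(self):
        rules = RuleParams(kT1=2.0, kTreg=1.0)
        env = MediatorEnvironment(pd1_occupancy=1.0)
        assert exhaustion_probability(0, 5, env, rules, 1.0) == 0.0

    def test_tregs_add_to_exhaustion(self):
        rules = RuleParams(kT1=0.5, kTreg=0.5)
        env = MediatorEnvironment()
        p0 = exhaustion_probability(0, 1, env, rules, 1.0)
        p2 = exhaustion_probability(2, 1, env, rules, 1.0)
        assert p2 > p0


class TestTregExpansion:
    def test_no_arginase_no_expansion(self):
        assert treg_expansion_probability(
            MediatorEnvironment(ArgI=0.0), RuleParams(), 1.0) == 0.0

    def test_capacity_cap(self):
        rules = RuleParams(Treg_max=1e5)
        env = MediatorEnvironment(ArgI=1e6, treg_density=1e5)
        assert treg_expansion_probability(env, rules, 1.0) == 0.0

    def test_monotone_in_arginase(self):
        rules = RuleParams()
        lo = treg_expansion_probability(MediatorEnvironment(ArgI=1.0), rules, 1.0)
        hi = treg_expansion_probability(MediatorEnvironment(ArgI=100.0), rules, 1.0)
        assert hi > lo > 0.0


class TestLineage:
    def test_lineage_conservation_without_death(self):
        """No killing/death: total cancer agents created equals
        1 + number of successful divisions, exactly."""
        rules = RuleParams(k=0.5, r_st=1.0, r_p=1.0, d_max=6, mu=0.0,
                           u_st=3.0, u_p=3.0, u_T=0.0)
        w = grow_only_world(rules, n=18, seed=21)
        w.run(8.0)
        created = w._next_id          # ids are never reused
        alive = sum(w.census[k] for k in (CSC, PC, SC))
        assert alive == created       # nothing ever removed
        assert created >= 1
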