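import numpy as np
import pytest

from spqsp.agents import RuleParams
from spqsp.coupling import CouplingState, World
from spqsp.lattice import GridSpec
from spqsp.qsp import QSPParams


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(12345))


@pytest.fixture
def small_grid():
    return GridSpec(8, 8, 8)


def make_world(grid=None, rules=None, qsp=None, gamma=1.0, tau=0.25,
               seed=0, rv=0.1, mode="roi", **world_kw) -> World:
    """A bare world (no agents) with quiet whole-patient dynamics."""
    grid = grid or GridSpec(12, 12, 12)
    rules = rules or RuleParams()
    qsp = qsp or QSPParams(kC1_growth=0.0, kC_T1=0.0, k_prime=0.0,
                           k_MDSC_base=0.0, k_MDSC_ccl2=0.0)
    w = World(grid, qsp, rules, CouplingState(gamma=gamma, tau=tau, mode=mode),
              seed=seed, rv_fraction=rv, **world_kw)
    w._sync_qsp_from_census()
    w.coupling.initialized = True
    return w


@pytest.fixture
def bare_world():
    return make_world()
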