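"""Stochastic state machines for every agent kind on the lattice.

Cancer cells come in three behavioral flavors: stem-like cells (CSC) divide
indefinitely, symmetrically (two CSCs) or asymmetrically (CSC + progenitor);
progenitor cells (PC) carry a division budget ``d_max`` and turn senescent
when it is spent; senescent cells (SC) only die, at rate ``mu``.  CD8+
T cells enter as effectors (Teff), become cytotoxic (Tcyt) on contact with
cancer, and are exhausted (Texh) through PD-1/PD-L1 engagement or by
neighboring regulatory T cells (Treg).  Tregs expand under arginase-I up to
a density cap; MDSCs only migrate, decay, and source the suppressive
mediators tracked by the whole-patient model.

Every stochastic event follows the propensity convention: an event with
rate ``a`` (day^-1) fires during a step of length ``dt`` with probability
``1 - exp(-a*dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .lattice import (CSC, MDSC, PC, SC, TCYT, TEFF, TEXH, TREG,
                      _pick_admissible)


@dataclass(slots=True)
class CellAgent:
    """One lattice agent; ``divisions_done`` is meaningful for PCs only."""

    id: int
    kind: int
    position: tuple[int, int, int]
    divisions_done: int = 0


@dataclass
class RuleParams:
    """Parameters of the agent rules (rates in day^-1 unless noted)."""

    k: float = 0.95           # probability a CSC division is asymmetric
    d_max: int = 9            # PC division budget
    mu: float = 0.05          # SC death rate
    r_st: float = 0.05        # CSC division rate
    r_p: float = 0.1          # PC division rate
    u_st: float = 4.0         # CSC migration rate
    u_p: float = 4.0          # PC migration rate
    u_sc: float = 0.0         # SC migration rate
    u_T: float = 10.0         # T cell migration rate (all subtypes)
    u_mdsc: float = 4.0       # MDSC migration rate
    # reaction rates shared with the whole-patient model
    kC_T1: float = 1.43       # killing of cancer by cytotoxic T cells
    kT1: float = 0.1          # exhaustion via PD-L1
    kTreg: float = 0.0893     # exhaustion by neighboring Tregs (per Treg)
    d_T: float = 0.1          # Teff/Tcyt/Texh death rate
    d_Treg: float = 0.1
    d_MDSC: float = 0.2
    k_T0_exp: float = 0.2     # Treg expansion rate at Arg-I saturation
    Treg_max: float = 2e6     # cell/mL, expansion capacity
    # Hill half-max constants
    K_NO: float = 1.0         # ng/mL
    K_Arg_kill: float = 40.0  # ng/mL
    K_Arg_exp: float = 20.0   # ng/mL
    K_PD1: float = 0.5        # unbound-PD-1 fraction at half effect
    K_PDL1: float = 1.0       # neighborhood PD-L1+ cells at half effect

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must be in [0, 1]")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"parameter {f.name} must be non-negative")

    def with_overrides(self, **kw) -> "RuleParams":
        return replace(self, **kw)

    def migration_rate(self, kind: int) -> float:
        return {CSC: self.u_st, PC: self.u_p, SC: self.u_sc, MDSC: self.u_mdsc,
                TEFF: self.u_T, TCYT: self.u_T, TEXH: self.u_T,
                TREG: self.u_T}[kind]


@dataclass(frozen=True)
class MediatorEnvironment:
    """Spatially uniform mediator levels fed to the rules each step, read
    from the whole-patient model at the start of the step."""

    ArgI: float = 0.0
    NO: float = 0.0
    pd1_occupancy: float = 0.0
    treg_density: float = 0.0   # cell/mL, whole-tumor Treg density


def event_probability(rate: float, dt: float) -> float:
    """P(event in dt) for a Poisson propensity: 1 - exp(-rate*dt)."""
    if rate < 0:
        raise ValueError("propensity must be non-negative")
    return -np.expm1(-rate * dt)


def _spawn(world, kind: int, voxel: int, divisions: int = 0) -> CellAgent:
    """Create an agent in ``voxel`` through the world's bookkeeping."""
    return world.add_agent(kind, world.grid.unflat(voxel), divisions)


def csc_division(cell: CellAgent, params: RuleParams, world,
                 rng: np.random.Generator, dt: float) -> CellAgent | None:
    """CSC division: daughter into a uniformly chosen admissible neighbor.

    With probability ``k`` the division is asymmetric (daughter is a PC
    with a fresh division budget), otherwise symmetric (daughter CSC).
    The mother always remains a CSC; divisions abort without effect when
    every neighbor voxel is blocked.
    """
    if rng.random() >= event_probability(params.r_st, dt):
        return None
    here = world.grid.flat(cell.position)
    target = _pick_admissible(CSC, world.neighbor_flats(here), world.occupancy, rng)
    if target is None:
        return None
    kind = PC if rng.random() < params.k else CSC
    return _spawn(world, kind, target)


def pc_division_or_senescence(cell: CellAgent, params: RuleParams, world,
                              rng: np.random.Generator, dt: float) -> CellAgent | None:
    """PC division at rate ``r_p``; both daughters inherit the incremented
    division count and any PC reaching ``d_max`` turns senescent."""
    if cell.divisions_done >= params.d_max:
        world.retype_large(cell, SC)
        return None
    if rng.random() >= event_probability(params.r_p, dt):
        return None
    here = world.grid.flat(cell.position)
    target = _pick_admissible(PC, world.neighbor_flats(here), world.occupancy, rng)
    if target is None:
        return None
    cell.divisions_done += 1
    daughter = _spawn(world, PC, target, divisions=cell.divisions_done)
    if cell.divisions_done >= params.d_max:
        world.retype_large(cell, SC)
        world.retype_large(daughter, SC)
    return daughter


def sc_death(cell: CellAgent, mu: float, dt: float,
             rng: np.random.Generator) -> bool:
    """Senescent-cell death: True if the cell is to be removed."""
    return rng.random() < event_probability(mu, dt)


def tcell_activation(cell: CellAgent, n_cancer_neighborhood: int) -> int:
    """Teff -> Tcyt iff at least one cancer cell occupies the same voxel or
    the 26-voxel Moore neighborhood; returns the (possibly new) kind."""
    if cell.kind != TEFF:
        return cell.kind
    return TCYT if n_cancer_neighborhood > 0 else TEFF


def killing_probability(n_cyt: int, env: MediatorEnvironment,
                        params: RuleParams, dt: float) -> float:
    """P(a cancer cell is killed) given ``n_cyt`` cytotoxic T cells in its
    neighborhood, with Hill inhibition by NO and Arg-I and restoration of
    killing under PD-1 blockade."""
    if n_cyt <= 0:
        return 0.0
    f_no = params.K_NO / (params.K_NO + env.NO)
    f_arg = params.K_Arg_kill / (params.K_Arg_kill + env.ArgI)
    f_pd1 = params.K_PD1 / (params.K_PD1 + (1.0 - env.pd1_occupancy))
    return event_probability(params.kC_T1 * n_cyt * f_no * f_arg * f_pd1, dt)


def kill_cancer(cell: CellAgent, n_cyt: int, env: MediatorEnvironment,
                params: RuleParams, dt: float, rng: np.random.Generator) -> bool:
    """True if the cancer cell dies to cytotoxic T cell attack this step."""
    p = killing_probability(n_cyt, env, params, dt)
    return p > 0.0 and rng.random() < p


def exhaustion_probability(n_treg: int, n_pdl1: int, env: MediatorEnvironment,
                           params: RuleParams, dt: float) -> float:
    """P(Tcyt -> Texh) from PD-L1 engagement (suppressed by drug occupancy
    of PD-1) plus neighboring-Treg inhibition."""
    g_pdl1 = n_pdl1 / (n_pdl1 + params.K_PDL1) if n_pdl1 > 0 else 0.0
    rate = (params.kT1 * g_pdl1 * (1.0 - env.pd1_occupancy)
            + params.kTreg * n_treg)
    return event_probability(rate, dt)


def tcell_exhaustion(cell: CellAgent, n_treg: int, n_pdl1: int,
                     env: MediatorEnvironment, params: RuleParams,
                     dt: float, rng: np.random.Generator) -> bool:
    """True if the cytotoxic T cell becomes exhausted this step."""
    return rng.random() < exhaustion_probability(n_treg, n_pdl1, env, params, dt)


def treg_expansion_probability(env: MediatorEnvironment, params: RuleParams,
                               dt: float) -> float:
    """Treg division probability: activated by Arg-I, capped at Treg_max."""
    act = env.ArgI / (env.ArgI + params.K_Arg_exp) if env.ArgI > 0 else 0.0
    cap = max(0.0, 1.0 - env.treg_density / params.Treg_max)
    return event_probability(params.k_T0_exp * act * cap, dt)


def treg_expansion(cell: CellAgent, env: MediatorEnvironment,
                   params: RuleParams, world, rng: np.random.Generator,
                   dt: float) -> CellAgent | None:
    """Treg division into an admissible neighbor voxel, or None."""
    if rng.random() >= treg_expansion_probability(env, params, dt):
        return None
    here = world.grid.flat(cell.position)
    target = _pick_admissible(TREG, world.neighbor_flats(here), world.occupancy, rng)
    if target is None:
        return None
    return _spawn(world, TREG, target)


def generic_decay(cell: CellAgent, rate: float, dt: float,
                  rng: np.random.Generator) -> bool:
    """First-order death of any agent kind: True if removed this step."""
    return rng.random() < event_probability(rate, dt)
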