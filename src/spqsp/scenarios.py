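"""Ready-made simulation scenarios at desk scale.

Each scenario freezes a parameter regime of the hybrid model — the three
morphology regimes of the tumor-growth study, the slow/medium/fast
immune-response regimes, a well-mixed self-consistency setup and a
quasi-1D traveling-front setup — on grids and durations small enough to
run in minutes.  Absolute division and migration rates are not part of the
regime definitions (only their dimensionless combinations are), so the
values here are documented desk-scale defaults; full-size grids can be
requested with ``full_size=True``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .agents import RuleParams
from .coupling import CouplingState, World
from .invasive_front import kpp_wave_profile
from .lattice import GridSpec, lattice_diffusivity
from .qsp import DoseSchedule, QSPParams


@dataclass
class Scenario:
    """A fully specified run: grid, parameters, coupling, schedule."""

    name: str
    grid: GridSpec
    rule_params: RuleParams
    qsp_params: QSPParams
    coupling: CouplingState
    dose: DoseSchedule = field(default_factory=lambda: DoseSchedule(enabled=False))
    rv_fraction: float = 0.1
    duration: float = 20.0            # days
    seed: int = 0
    init_policy: str = "single_cell"
    init_kwargs: dict[str, Any] = field(default_factory=dict)
    initial_qsp: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["grid"] = GridSpec(**d["grid"])
        d["rule_params"] = RuleParams(**d["rule_params"])
        d["qsp_params"] = QSPParams(**d["qsp_params"])
        d["coupling"] = CouplingState(**d["coupling"])
        d["dose"] = DoseSchedule(**d["dose"])
        return cls(**d)

    def build_world(self, seed: int | None = None) -> World:
        world = World(self.grid, self.qsp_params, self.rule_params,
                      replace(self.coupling, initialized=False),
                      seed=self.seed if seed is None else seed,
                      dose=self.dose, rv_fraction=self.rv_fraction)
        for k, v in self.initial_qsp.items():
            setattr(world.qsp_state, k, v)
        world.initialize_coupling(policy=self.init_policy, **self.init_kwargs)
        return world


def fig3_scenarios(full_size: bool = False) -> dict[str, Scenario]:
    """The three tumor-morphology regimes grown from a single central CSC.

    A: R < 1, k = 0.95, d_max = 18 (fingering, detached groups);
    B: R ~ 1, k = 0.75, d_max = 18 (sparse);
    C: R ~ 1, k = 0.95, d_max = 9  (denser, more senescence).
    γ = 1 and immune recruitment is switched off in all three.
    """
    n = 150 if full_size else 60
    grid = GridSpec(n, n, n)
    qsp = QSPParams(k_prime=0.0, k_MDSC_base=0.0, k_MDSC_ccl2=0.0,
                    kC_T1=0.0, C_max=1e12)
    base = dict(mu=0.02, r_p=0.5, u_p=10.0, u_T=10.0)
    duration = 480.0 if full_size else 16.0
    coupling = CouplingState(gamma=1.0, tau=0.25)

    def make(name, **kw):
        return Scenario(name=name, grid=grid,
                        rule_params=RuleParams(**base, **kw), qsp_params=qsp,
                        coupling=replace(coupling), duration=duration,
                        init_policy="single_cell")

    return {
        "fig3_a": make("fig3_a", k=0.95, d_max=18, r_st=0.25, u_st=50.0),  # R=0.1
        "fig3_b": make("fig3_b", k=0.75, d_max=18, r_st=0.25, u_st=5.0),   # R=1
        "fig3_c": make("fig3_c", k=0.95, d_max=9, r_st=0.25, u_st=5.0),    # R=1
    }


#: growth-regime table: (kC1_growth, growth/killing ratio,
#:  PD-L1/Treg exhaustion ratio, Treg_max, R)
_GROWTH_REGIMES = {
    "slow": (0.005, 7e-3, 0.56, 9e5, 1.0 / 50.0),
    "medium": (0.01, 7e-3, 1.12, 2e6, 1.0),
    "fast": (0.015, 1.1e-2, 1.12, 2e6, 50.0),
}


def table4_scenarios(dosing: bool = False, full_size: bool = False,
                     ) -> dict[str, Scenario]:
    """Slow/medium/fast growth regimes on a thin tumor-slice grid.

    The regimes are pinned by the growth rate (0.005, 0.01, 0.015 per day),
    the growth-to-killing ratio, the PD-L1-to-Treg exhaustion ratio, the
    Treg density cap and the morphology ratio R (1/50, 1, 50).  The lattice
    division rate of progenitors is matched to the compartmental growth
    rate, CSC rates then follow from R with the migration defaults below.
    The slice is seeded with a developed radial front (a grown tumor
    occupying the slab center) so that front analytics apply from day one.
    """
    kTreg = 0.0893
    nx = 260
    nz = 20 if full_size else 1
    grid = GridSpec(nx, nx, nz)
    out = {}
    for name, (kg, ratio_gk, ratio_exh, treg_max, R) in _GROWTH_REGIMES.items():
        kC_T1 = kg / ratio_gk
        kT1 = ratio_exh * kTreg
        r_p = kg
        u_p = 4.0
        # CSC rates from R = (r_st u_p)/(r_p u_st); slow growth keeps CSC
        # migration dominant, fast growth CSC proliferation dominant
        u_st = 8.0 if R < 1 else (4.0 if R == 1 else 0.8)
        r_st = R * r_p * u_st / u_p
        rules = RuleParams(k=0.95, d_max=9, mu=0.02, r_st=r_st, r_p=r_p,
                           u_st=u_st, u_p=u_p, u_T=10.0, u_mdsc=4.0,
                           kC_T1=kC_T1, kT1=kT1, kTreg=kTreg,
                           Treg_max=treg_max)
        qsp = QSPParams(kC1_growth=kg, kC_T1=kC_T1, kT1=kT1, kTreg=kTreg,
                        Treg_max=treg_max, C_max=1e12,
                        k_prime=100.0, k_LN_out=0.5, K_antigen=1e3,
                        k_T1_rec=0.1, k_T0_rec=0.05,
                        k_MDSC_base=2.0, k_MDSC_ccl2=4.0,
                        K_presence=0.0)
        dose = DoseSchedule(dose_mg_per_kg=3.0, interval=14.0,
                            enabled=dosing)
        sc = Scenario(
            name=f"table4_{name}" + ("_dosed" if dosing else ""),
            grid=grid, rule_params=rules, qsp_params=qsp,
            coupling=CouplingState(gamma=1.0, tau=0.25),
            dose=dose, rv_fraction=0.1, duration=30.0,
            init_policy="developed_front",
            init_kwargs={"core_radius_mm": 0.9, "csc_fraction": 0.05},
            initial_qsp={"T1_central": 100.0, "T0_central": 50.0},
        )
        out[name] = sc
    return out


def _front_profile(scenario: Scenario) -> tuple[float, float]:
    """Continuum-matched (D, r) of the scenario's progenitor population."""
    D = lattice_diffusivity(scenario.rule_params.u_p, scenario.coupling.tau,
                            scenario.grid)
    return D, scenario.rule_params.r_p


def build_front_world(scenario: Scenario, seed: int | None = None) -> World:
    """Build a world for a slab scenario seeded with a developed front.

    The radial cancer density follows the Fisher–KPP traveling-wave profile
    of the scenario's own progenitor diffusivity and division rate, centred
    in the slab, so that the invasive front starts from its asymptotic
    shape instead of spending months developing one.
    """
    D, r = _front_profile(scenario)
    z, U = kpp_wave_profile(D, r)
    core = scenario.init_kwargs.get("core_radius_mm", 1.0)
    csc_fraction = scenario.init_kwargs.get("csc_fraction", 0.05)

    world = World(scenario.grid, scenario.qsp_params, scenario.rule_params,
                  replace(scenario.coupling, initialized=False),
                  seed=scenario.seed if seed is None else seed,
                  dose=scenario.dose, rv_fraction=scenario.rv_fraction)
    for k, v in scenario.initial_qsp.items():
        setattr(world.qsp_state, k, v)
    # voxel-wise Bernoulli occupancy equal to the wave profile: the core
    # plateau fills to ~1, the tail thins out exactly as U(z)
    g = scenario.grid
    cx, cy = (g.nx - 1) / 2.0, (g.ny - 1) / 2.0
    xs = np.arange(g.nx) - cx
    ys = np.arange(g.ny) - cy
    rr = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2) * g.L_mm
    dens = np.interp(rr - core, z, U, left=1.0, right=0.0)
    rng = world.rng_init
    for iz in range(g.nz):
        occ = rng.random(dens.shape) < dens
        for ix, iy in zip(*np.nonzero(occ)):
            kind = 1 if rng.random() < csc_fraction else 2   # CSC or PC
            world.add_agent(kind, (int(ix), int(iy), iz))
    world.t = world.qsp_state.t
    world._sync_qsp_from_census()
    world.coupling.initialized = True
    return world


def wellmixed_scenario(n_initial: int = 20) -> Scenario:
    """Linear well-mixed setup for the ODE/lattice self-consistency check.

    Symmetric-only CSC division (pure branching growth), no killing, no
    exhaustion, no expansion; T cells and MDSCs are recruited from a
    central compartment that drains identically in the pure-ODE and coupled
    runs.  Every rule is then linear, so the coupled means must track the
    ODE solution.
    """
    grid = GridSpec(24, 24, 24)
    rules = RuleParams(k=0.0, d_max=9, mu=0.0, r_st=0.1, r_p=0.1,
                       u_st=5.0, u_p=5.0, u_T=10.0, u_mdsc=5.0,
                       kC_T1=0.0, kT1=0.0, kTreg=0.0, k_T0_exp=0.0,
                       d_T=0.1, d_Treg=0.1, d_MDSC=0.2)
    qsp = QSPParams(kC1_growth=0.1, C_max=1e15, kC_T1=0.0, kT1=0.0,
                    kTreg=0.0, k_T0_exp=0.0, k_prime=0.0,
                    k_T1_rec=0.1, k_T0_rec=0.05,
                    k_MDSC_base=5.0, k_MDSC_ccl2=0.0,
                    d_T1=0.1, d_T0=0.1, d_MDSC=0.2,
                    d_T1_central=0.01, d_T0_central=0.01,
                    K_presence=0.0, k_sec_Arg=0.0, k_sec_NO=0.0,
                    k_sec_CCL2=0.0)
    return Scenario(
        name="wellmixed", grid=grid, rule_params=rules, qsp_params=qsp,
        coupling=CouplingState(gamma=1.0, tau=0.05), rv_fraction=0.1,
        duration=15.0, init_policy="wellmixed",
        init_kwargs={"n_initial": n_initial},
        initial_qsp={"T1_central": 500.0, "T0_central": 300.0},
    )


def build_wellmixed_world(scenario: Scenario, seed: int = 0) -> World:
    """Seed ``n_initial`` CSCs at uniform random voxels, counts synced."""
    world = World(scenario.grid, scenario.qsp_params, scenario.rule_params,
                  replace(scenario.coupling, initialized=False), seed=seed,
                  dose=scenario.dose, rv_fraction=scenario.rv_fraction)
    for k, v in scenario.initial_qsp.items():
        setattr(world.qsp_state, k, v)
    n = scenario.init_kwargs.get("n_initial", 20)
    placed = 0
    while placed < n:
        vox = int(world.rng_init.integers(world.grid.n_voxels))
        if world.occupancy.can_place(1, vox):
            world.add_agent(1, world.grid.unflat(vox))
            placed += 1
    world._sync_qsp_from_census()
    world.coupling.initialized = True
    return world


def kpp_front_scenario() -> Scenario:
    """Quasi-1D strip for measuring the invasion-front speed.

    A fully occupied slab of progenitors at one end invades the empty strip;
    the front should travel at about the Fisher–KPP minimal speed
    2 sqrt(r_p D_p) for the continuum-matched diffusivity (stochastic
    fronts at finite per-site occupancy run a little slower).
    """
    grid = GridSpec(200, 40, 1)
    rules = RuleParams(k=1.0, d_max=30, mu=0.0, r_st=0.0, r_p=0.1,
                       u_st=0.0, u_p=16.0, u_T=0.0)
    qsp = QSPParams(kC1_growth=0.1, C_max=1e12, kC_T1=0.0, k_prime=0.0,
                    k_MDSC_base=0.0, k_MDSC_ccl2=0.0)
    return Scenario(name="kpp_front", grid=grid, rule_params=rules,
                    qsp_params=qsp, coupling=CouplingState(gamma=1.0, tau=0.05),
                    rv_fraction=0.01, duration=100.0, init_policy="front_slab",
                    init_kwargs={"n_columns": 15})


def build_kpp_front_world(scenario: Scenario, seed: int = 0) -> World:
    """Fill the first ``n_columns`` of the strip with progenitor cells."""
    world = World(scenario.grid, scenario.qsp_params, scenario.rule_params,
                  replace(scenario.coupling, initialized=False), seed=seed,
                  rv_fraction=scenario.rv_fraction)
    ncol = scenario.init_kwargs.get("n_columns", 15)
    for x in range(ncol):
        for y in range(scenario.grid.ny):
            world.add_agent(2, (x, y, 0))   # PC
    world._sync_qsp_from_census()
    world.coupling.initialized = True
    return world


def synthetic_radial_tumor(radius_mm: float = 1.0, front_width_mm: float = 0.2,
                           n_tcells: int = 400, seed: int = 0,
                           extent_mm: float = 4.0, pixel_mm: float = 0.02,
                           tcell_ring_mm: float | None = None,
                           tcell_ring_width_mm: float = 0.15,
                           ) -> tuple[pd.DataFrame, dict]:
    """Synthetic snapshot of a radially monotone tumor (test input).

    Cancer cells occupy lattice sites with probability following a logistic
    front 1/(1+exp((r-radius)/width)) (a hard disc when the width is zero);
    T cells are drawn from a Gaussian ring (default centred on the front).
    Returns the snapshot table (same schema as the simulator writes) and
    the ground-truth parameters.  Same seed, same table.
    """
    if radius_mm <= 0 or front_width_mm < 0:
        raise ValueError("radius must be positive, width non-negative")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    n = int(round(extent_mm / pixel_mm))
    c = (n - 1) / 2.0
    xs = (np.arange(n) - c) * pixel_mm
    rr = np.sqrt(xs[:, None] ** 2 + xs[None, :] ** 2)
    if front_width_mm == 0:
        p = (rr <= radius_mm).astype(float)
    else:
        p = 1.0 / (1.0 + np.exp((rr - radius_mm) / front_width_mm))
    occ = rng.random(p.shape) < p
    ix, iy = np.nonzero(occ)
    rows = [{"t_day": 0.0, "cell_id": i, "kind": "PC", "state": 0,
             "ix": int(x), "iy": int(y), "iz": 0}
            for i, (x, y) in enumerate(zip(ix, iy))]
    ring = radius_mm if tcell_ring_mm is None else tcell_ring_mm
    base = len(rows)
    for i in range(n_tcells):
        r = rng.normal(ring, tcell_ring_width_mm)
        th = rng.uniform(0.0, 2.0 * math.pi)
        x = int(round(c + r * math.cos(th) / pixel_mm))
        y = int(round(c + r * math.sin(th) / pixel_mm))
        if 0 <= x < n and 0 <= y < n:
            rows.append({"t_day": 0.0, "cell_id": base + i, "kind": "Teff",
                         "state": 0, "ix": x, "iy": y, "iz": 0})
    truth = {"radius_mm": radius_mm, "front_width_mm": front_width_mm,
             "tcell_ring_mm": ring, "extent_mm": extent_mm,
             "pixel_mm": pixel_mm, "seed": seed}
    return pd.DataFrame(rows), truth


SCENARIO_BUILDERS = {
    "wellmixed": (wellmixed_scenario, build_wellmixed_world),
    "kpp_front": (kpp_front_scenario, build_kpp_front_world),
}


def get_scenario(name: str, dosing: bool = False) -> Scenario:
    """Look up a named scenario (fig3_a/b/c, table4_slow/medium/fast,
    wellmixed, kpp_front)."""
    if name in ("fig3_a", "fig3_b", "fig3_c"):
        return fig3_scenarios()[name]
    if name.startswith("table4_"):
        key = name.removeprefix("table4_").removesuffix("_dosed")
        dosed = dosing or name.endswith("_dosed")
        return table4_scenarios(dosing=dosed)[key]
    if name == "wellmixed":
        return wellmixed_scenario()
    if name == "kpp_front":
        return kpp_front_scenario()
    raise KeyError(f"unknown scenario {name!r}")


def build_world_for(scenario: Scenario, seed: int | None = None) -> World:
    """Dispatch to the right builder for the scenario's init policy."""
    if scenario.init_policy == "developed_front":
        return build_front_world(scenario, seed=seed)
    if scenario.init_policy == "wellmixed":
        return build_wellmixed_world(scenario, seed=scenario.seed if seed is None else seed)
    if scenario.init_policy == "front_slab":
        return build_kpp_front_world(scenario, seed=scenario.seed if seed is None else seed)
    return scenario.build_world(seed=seed)
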