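"""Coupling of the whole-patient ODE model to the on-lattice tumor.

A constant scaling factor γ ties the two representations together: one
lattice agent stands for γ real cells, so QSP tumor counts map onto the
lattice by floor division (scaling) and the lattice census maps back by
multiplication (inverse scaling).  Each coupling step of length τ:

1. the whole-patient state at time t supplies mediator levels, PD-1
   occupancy and recruitment fluxes to the agent rules;
2. agents migrate, then react (divide, kill, exhaust, expand, die), then
   new T cells and MDSCs are recruited at vascular entry points with a
   probability biased toward the invasive front;
3. the agent census, times γ, overwrites the QSP tumor compartment;
4. the ODE system is advanced to t+τ with the tumor cell species frozen
   (they are owned by the lattice from initialization onward).

With γ > 1 the lattice acts as a coarse-grained whole-tumor model; agent
migration rates are then rescaled by γ^(-1/3) so that a super-cell agent
moves as far as the cell packet it represents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import agents as ar
from .agents import CellAgent, MediatorEnvironment, RuleParams
from .lattice import (CANCER_KINDS, CSC, KIND_NAMES, MDSC, PC, SC,
                      TCELL_KINDS, TCYT, TEFF, TEXH, TREG, GridSpec,
                      VoxelOccupancy, migration_probability, move_offsets,
                      neighbors)
from .qsp import (DoseSchedule, QSPParams, QSPState, advance_qsp, apply_dose,
                  recruitment_fluxes, tumor_volume)

log = logging.getLogger(__name__)

def _box_sum(grid_arr: np.ndarray) -> np.ndarray:
    """Moore-neighborhood (3x3x3 box, incl. own voxel) sum of a count grid."""
    out = grid_arr.astype(np.float32)
    for axis in range(out.ndim):
        if grid_arr.shape[axis] > 1:
            out = ndimage.uniform_filter1d(out, size=3, axis=axis,
                                           mode="constant") * 3.0
    return np.rint(out).astype(np.int32)


@dataclass
class CouplingState:
    """γ, τ and the run mode ('roi' = region of interest at true cell
    resolution, 'coarse' = whole tumor with super-cell agents)."""

    gamma: float = 1.0
    tau: float = 0.25           # day; also the lattice step dt
    mode: str = "roi"
    initialized: bool = False

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.mode not in ("roi", "coarse"):
            raise ValueError("mode must be 'roi' or 'coarse'")


@dataclass
class RecruitmentField:
    """Vascular entry points: one recruitment point per selected voxel,
    with density-dependent weights normalized to mean 1."""

    entry_voxels: np.ndarray            # flat voxel indices
    rv_fraction: float
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.rv_fraction <= 1.0:
            raise ValueError("rv_fraction must be in (0, 1]")
        if self.weights is None:
            self.weights = np.ones(len(self.entry_voxels))


def scale_qsp_to_abm(count: float, gamma: float) -> int:
    """Number of lattice agents representing ``count`` QSP cells: floor(count/γ)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return int(math.floor(count / gamma))


def inverse_scale_abm_to_qsp(census: dict[int, int], gamma: float) -> dict[str, float]:
    """QSP tumor counts from the agent census: γ times the kind sums; the
    effector and cytotoxic pools map jointly onto the QSP effector count."""
    g = float(gamma)
    return {
        "C": g * (census.get(CSC, 0) + census.get(PC, 0) + census.get(SC, 0)),
        "T1": g * (census.get(TEFF, 0) + census.get(TCYT, 0)),
        "Texh": g * census.get(TEXH, 0),
        "T0": g * census.get(TREG, 0),
        "MDSC": g * census.get(MDSC, 0),
    }


def recruitment_probability(a: float, gamma: float, tau: float) -> float:
    """P(one recruitment event at one entry point per step):
    1 - exp(-a·τ/γ) for propensity ``a`` (day^-1 in QSP cell units)."""
    if a < 0:
        raise ValueError("propensity must be non-negative")
    return -np.expm1(-a * tau / gamma)


def place_entry_points(grid: GridSpec, rv_fraction: float,
                       rng: np.random.Generator) -> RecruitmentField:
    """Sample round(rv_fraction x total voxels) distinct entry voxels
    uniformly without replacement (at most one point per voxel)."""
    if not 0.0 < rv_fraction <= 1.0:
        raise ValueError("rv_fraction must be in (0, 1]")
    n = int(round(rv_fraction * grid.n_voxels))
    chosen = rng.choice(grid.n_voxels, size=n, replace=False)
    return RecruitmentField(entry_voxels=np.sort(chosen), rv_fraction=rv_fraction)


def recruitment_weight(rho: np.ndarray | float, band: tuple[float, float] = (0.05, 0.5),
                       w0: float = 0.1, peak: float = 1.0) -> np.ndarray | float:
    """Unnormalized recruitment weight as a function of the local normalized
    cancer density ρ: a piecewise-linear bump peaking at the middle of the
    invasive-front density band, with floor ``w0`` elsewhere (cells are
    recruited everywhere, but preferentially at the front)."""
    lo, hi = band
    if not 0.0 <= lo < hi:
        raise ValueError("invalid density band")
    rho = np.asarray(rho, dtype=float)
    mid = 0.5 * (lo + hi)
    up = w0 + (peak - w0) * (rho - lo) / (mid - lo)
    down = w0 + (peak - w0) * (hi - rho) / (hi - mid)
    w = np.where(rho < mid, up, down)
    w = np.where((rho < lo) | (rho > hi), w0, w)
    return w if w.ndim else float(w)


def coarse_grain_rates(params: RuleParams, gamma: float) -> RuleParams:
    """Rescale migration rates by γ^(-1/3) for the coarse-grained mode
    (an agent then moves as the cell packet it represents); reaction rates
    are left untouched."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    f = gamma ** (-1.0 / 3.0)
    return params.with_overrides(
        u_st=params.u_st * f, u_p=params.u_p * f, u_sc=params.u_sc * f,
        u_T=params.u_T * f, u_mdsc=params.u_mdsc * f)


class World:
    """The coupled simulation: lattice, agents, whole-patient state."""

    def __init__(self, grid: GridSpec, qsp_params: QSPParams,
                 rule_params: RuleParams, coupling: CouplingState,
                 seed: int = 0, dose: DoseSchedule | None = None,
                 rv_fraction: float = 0.1,
                 recruitment_band: tuple[float, float] = (0.05, 0.5),
                 recruitment_floor: float = 0.1,
                 density_sigma_voxels: float = 3.0):
        self.grid = grid
        self.qsp_params = qsp_params
        self.coupling = coupling
        self.rule_params = (coarse_grain_rates(rule_params, coupling.gamma)
                            if coupling.mode == "coarse" else rule_params)
        self.dose = dose or DoseSchedule(enabled=False)
        self.recruitment_band = recruitment_band
        self.recruitment_floor = recruitment_floor
        self.density_sigma_voxels = density_sigma_voxels

        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(5)
        self.rng_init = np.random.Generator(np.random.Philox(kids[0]))
        self.rng_migration = np.random.Generator(np.random.Philox(kids[1]))
        self.rng_reactions = np.random.Generator(np.random.Philox(kids[2]))
        self.rng_recruitment = np.random.Generator(np.random.Philox(kids[3]))
        self.rng_shuffle = np.random.Generator(np.random.Philox(kids[4]))

        self.occupancy = VoxelOccupancy(grid)
        self._move_offsets = move_offsets(grid)
        self._nbr_cache: dict[int, list[int]] = {}
        self.agents: dict[int, CellAgent] = {}
        self._next_id = 0
        self.census: dict[int, int] = {k: 0 for k in KIND_NAMES}
        self.qsp_state = QSPState()
        self.recruitment: RecruitmentField = place_entry_points(
            grid, rv_fraction, self.rng_init)
        self.t = 0.0
        self.log_rows: list[dict] = []
        self.recruited_totals: dict[int, int] = {TEFF: 0, TREG: 0, MDSC: 0}

    # -- agent bookkeeping ----------------------------------------------
    def add_agent(self, kind: int, position: tuple[int, int, int],
                  divisions: int = 0) -> CellAgent:
        aid = self._next_id
        self._next_id += 1
        agent = CellAgent(aid, kind, position, divisions)
        self.occupancy.place(kind, self.grid.flat(position), aid)
        self.agents[aid] = agent
        self.census[kind] += 1
        return agent

    def remove_agent(self, agent: CellAgent) -> None:
        self.occupancy.remove(agent.kind, self.grid.flat(agent.position), agent.id)
        del self.agents[agent.id]
        self.census[agent.kind] -= 1

    def retype_large(self, agent: CellAgent, new_kind: int) -> None:
        self.occupancy.retype_large(new_kind, self.grid.flat(agent.position))
        self.census[agent.kind] -= 1
        self.census[new_kind] += 1
        agent.kind = new_kind

    def retype_tcell(self, agent: CellAgent, new_kind: int) -> None:
        self.occupancy.retype_tcell(agent.kind, new_kind,
                                    self.grid.flat(agent.position))
        self.census[agent.kind] -= 1
        self.census[new_kind] += 1
        agent.kind = new_kind

    def neighbor_flats(self, flat: int) -> list[int]:
        """Moore-neighbor flat indices of a voxel, cached on first use
        (division placement interrogates only the voxels where events
        actually happen)."""
        cached = self._nbr_cache.get(flat)
        if cached is None:
            pos = self.grid.unflat(flat)
            cached = [self.grid.flat(q) for q in neighbors(pos, self.grid)]
            self._nbr_cache[flat] = cached
        return cached

    # -- density and environment ----------------------------------------
    def cancer_count_grid(self) -> np.ndarray:
        lk = self.occupancy.large_kind.reshape(self.grid.shape)
        return ((lk == CSC) | (lk == PC) | (lk == SC)).astype(np.int16)

    def normalized_cancer_density(self) -> np.ndarray:
        """Gaussian-smoothed cancer occupancy, max-normalized to [0, 1]."""
        dens = ndimage.gaussian_filter(self.cancer_count_grid().astype(np.float32),
                                       sigma=self.density_sigma_voxels,
                                       mode="constant")
        m = float(dens.max())
        return dens / m if m > 0 else dens

    def mediator_environment(self) -> MediatorEnvironment:
        s, p = self.qsp_state, self.qsp_params
        v_t = max(s.C, 1.0) * p.cell_volume
        return MediatorEnvironment(ArgI=s.ArgI, NO=s.NO,
                                   pd1_occupancy=s.pd1_occupancy(p),
                                   treg_density=s.T0 / v_t)

    # -- initialization policies ----------------------------------------
    def seed_cancer_profile(self, n_agents: int, profile: str = "normal",
                            sigma_mm: float | None = None,
                            csc_fraction: float = 0.05,
                            radial_profile=None) -> int:
        """Place ``n_agents`` cancer agents around the grid center.

        ``profile``: 'single' (one CSC), 'normal' (3D Gaussian cloud),
        'sphere' (solid ball), or 'radial' (accept-reject against a caller
        supplied radial density ``radial_profile(r_mm) -> [0, 1]``).
        Returns the number actually placed (collisions are re-drawn, but a
        full neighborhood may truncate placement).
        """
        g, rng = self.grid, self.rng_init
        cx, cy, cz = (g.nx - 1) / 2.0, (g.ny - 1) / 2.0, (g.nz - 1) / 2.0
        if profile == "single":
            self.add_agent(CSC, (int(round(cx)), int(round(cy)), int(round(cz))))
            return 1
        L = g.L_mm
        placed = 0
        attempts = 0
        max_attempts = 200 * max(n_agents, 1)
        while placed < n_agents and attempts < max_attempts:
            attempts += 1
            if profile == "normal":
                s = (sigma_mm or 0.2) / L
                pos = (int(round(rng.normal(cx, s))), int(round(rng.normal(cy, s))),
                       int(round(rng.normal(cz, s * g.nz / g.nx if g.nz > 1 else 0.0))))
            elif profile == "sphere":
                rad = (sigma_mm or 0.2) / L
                while True:
                    d = rng.uniform(-rad, rad, size=3)
                    if d @ d <= rad * rad:
                        break
                if g.nz == 1:
                    d[2] = 0.0
                pos = (int(round(cx + d[0])), int(round(cy + d[1])),
                       int(round(cz + d[2])))
            elif profile == "radial":
                x = rng.integers(g.nx)
                y = rng.integers(g.ny)
                z = rng.integers(g.nz)
                r_mm = L * math.hypot(x - cx, y - cy)
                if rng.random() >= radial_profile(r_mm):
                    continue
                pos = (int(x), int(y), int(z))
            else:
                raise ValueError(f"unknown seeding profile {profile!r}")
            if not g.in_bounds(pos):
                continue
            if self.occupancy.can_place(CSC, g.flat(pos)):
                kind = CSC if rng.random() < csc_fraction else PC
                self.add_agent(kind, pos)
                placed += 1
        return placed

    def seed_immune_from_qsp(self) -> None:
        """Seed floor(count/γ) agents of each immune species at uniformly
        chosen admissible voxels (initialization-only; recruitment takes
        over afterwards)."""
        g = self.coupling.gamma
        s = self.qsp_state
        for kind, count in ((TEFF, s.T1), (TEXH, s.Texh), (TREG, s.T0),
                            (MDSC, s.MDSC)):
            n = scale_qsp_to_abm(count, g)
            placed = 0
            guard = 0
            while placed < n and guard < 100 * n + 100:
                guard += 1
                vox = int(self.rng_init.integers(self.grid.n_voxels))
                if self.occupancy.can_place(kind, vox):
                    self.add_agent(kind, self.grid.unflat(vox))
                    placed += 1

    def initialize_coupling(self, policy: str = "single_cell",
                            d0_mm: float | None = None,
                            t0: float | None = None,
                            max_time: float = 3650.0,
                            seed_kwargs: dict | None = None) -> None:
        """Start the hybrid run.

        ``single_cell``: lattice starts from one central CSC and the ODE
        tumor count starts at γ, both at t=0.  ``early``: the ODE model runs
        alone to ``t0`` (before appreciable immune recruitment), then cancer
        agents are seeded from the scaled count; no immune agents are
        seeded.  ``diameter_condition``: the ODE model runs alone until the
        equivalent spherical diameter reaches ``d0_mm``, then cancer and
        immune agents are seeded from the scaled counts.
        """
        sk = dict(seed_kwargs or {})
        if policy == "single_cell":
            self.seed_cancer_profile(1, profile="single")
        elif policy == "early":
            if t0 is None:
                raise ValueError("early policy needs t0")
            while self.qsp_state.t < t0:
                self.qsp_state = advance_qsp(
                    self.qsp_state, self.qsp_params,
                    min(self.coupling.tau, t0 - self.qsp_state.t))
            n = scale_qsp_to_abm(self.qsp_state.C, self.coupling.gamma)
            self.seed_cancer_profile(max(n, 1), **sk)
        elif policy == "diameter_condition":
            if d0_mm is None:
                raise ValueError("diameter_condition policy needs d0_mm")
            while True:
                _, diam = tumor_volume(self.qsp_state, self.qsp_params.cell_volume)
                if diam >= d0_mm:
                    break
                if self.qsp_state.t > max_time:
                    raise RuntimeError(
                        f"diameter {d0_mm} mm unreachable within {max_time} days")
                self.qsp_state = advance_qsp(self.qsp_state, self.qsp_params,
                                             self.coupling.tau)
            n = scale_qsp_to_abm(self.qsp_state.C, self.coupling.gamma)
            self.seed_cancer_profile(max(n, 1), **sk)
            self.seed_immune_from_qsp()
        else:
            raise ValueError(f"unknown policy {policy!r}")
        self.t = self.qsp_state.t
        self._sync_qsp_from_census()
        self.coupling.initialized = True

    # -- per-step passes -------------------------------------------------
    def _shuffled_agents(self) -> list[CellAgent]:
        order = list(self.agents.values())
        self.rng_shuffle.shuffle(order)
        return order

    def _migration_pass(self, dt: float) -> None:
        rng = self.rng_migration
        occ, grid = self.occupancy, self.grid
        offs = self._move_offsets
        n_offs = len(offs)
        p_by_kind = {k: migration_probability(self.rule_params.migration_rate(k), dt)
                     for k in KIND_NAMES}
        order = self._shuffled_agents()
        draws = rng.random(len(order))
        picks = rng.integers(n_offs, size=len(order))
        for agent, xi, j in zip(order, draws, picks):
            if xi >= p_by_kind[agent.kind]:
                continue
            dx, dy, dz = offs[j]
            x, y, z = agent.position
            q = (x + dx, y + dy, z + dz)
            if not grid.in_bounds(q):
                continue
            target = grid.flat(q)
            if not occ.can_place(agent.kind, target):
                continue
            here = grid.flat(agent.position)
            occ.remove(agent.kind, here, agent.id)
            occ.place(agent.kind, target, agent.id)
            agent.position = q

    def _reaction_pass(self, dt: float, env: MediatorEnvironment) -> None:
        rng = self.rng_reactions
        grid, occ = self.grid, self.occupancy
        par = self.rule_params
        shape = grid.shape
        any_t = any(self.census[k] for k in TCELL_KINDS)
        if any_t:
            cancer_nbh = _box_sum(self.cancer_count_grid()).ravel()
            tcyt_nbh = _box_sum(
                occ.kind_count[TCYT].reshape(shape)).ravel()
            treg_nbh = _box_sum(
                occ.kind_count[TREG].reshape(shape)).ravel()
            lk = occ.large_kind.reshape(shape)
            pdl1_nbh = _box_sum(((lk == CSC) | (lk == PC) | (lk == SC)
                                 | (lk == MDSC)).astype(np.int16)).ravel()
        for agent in self._shuffled_agents():
            if agent.id not in self.agents:   # removed earlier this pass
                continue
            kind = agent.kind
            here = grid.flat(agent.position)
            if kind in CANCER_KINDS and any_t:
                n_cyt = int(tcyt_nbh[here])
                if n_cyt and ar.kill_cancer(agent, n_cyt, env, par, dt, rng):
                    self.remove_agent(agent)
                    continue
            if kind == CSC:
                ar.csc_division(agent, par, self, rng, dt)
            elif kind == PC:
                ar.pc_division_or_senescence(agent, par, self, rng, dt)
            elif kind == SC:
                if ar.sc_death(agent, par.mu, dt, rng):
                    self.remove_agent(agent)
            elif kind == TEFF:
                # death and activation are not competing events: the state
                # change must not shield the cell from its death roll
                if ar.generic_decay(agent, par.d_T, dt, rng):
                    self.remove_agent(agent)
                elif ar.tcell_activation(agent, int(cancer_nbh[here])) == TCYT:
                    self.retype_tcell(agent, TCYT)
            elif kind == TCYT:
                if ar.tcell_exhaustion(agent, int(treg_nbh[here]),
                                       int(pdl1_nbh[here]), env, par, dt, rng):
                    self.retype_tcell(agent, TEXH)
                elif ar.generic_decay(agent, par.d_T, dt, rng):
                    self.remove_agent(agent)
            elif kind == TEXH:
                if ar.generic_decay(agent, par.d_T, dt, rng):
                    self.remove_agent(agent)
            elif kind == TREG:
                if ar.generic_decay(agent, par.d_Treg, dt, rng):
                    self.remove_agent(agent)
                else:
                    ar.treg_expansion(agent, env, par, self, rng, dt)
            elif kind == MDSC:
                if ar.generic_decay(agent, par.d_MDSC, dt, rng):
                    self.remove_agent(agent)

    def update_recruitment_weights(self) -> None:
        """Re-derive entry-point weights from the local cancer density:
        a bump over the invasive-front density band, renormalized to mean 1
        so total recruitment still matches the whole-patient budget."""
        rho = self.normalized_cancer_density().ravel()[self.recruitment.entry_voxels]
        w = recruitment_weight(rho, band=self.recruitment_band,
                               w0=self.recruitment_floor, peak=1.0)
        mean = float(np.mean(w))
        self.recruitment.weights = w / mean if mean > 0 else np.ones_like(w)

    def recruit_cells(self, dt: float) -> dict[int, int]:
        """Bernoulli recruitment at every entry point for every species.

        The whole-tumor flux F (cells/day) is split evenly over entry
        points and biased by the density weights (mean 1), so the expected
        lattice influx times γ equals F.
        """
        field_ = self.recruitment
        n_entry = len(field_.entry_voxels)
        recruited = {TEFF: 0, TREG: 0, MDSC: 0}
        if n_entry == 0:
            return recruited
        fluxes = recruitment_fluxes(self.qsp_state, self.qsp_params)
        gamma, rng = self.coupling.gamma, self.rng_recruitment
        for kind, name in ((TEFF, "Teff"), (TREG, "Treg"), (MDSC, "MDSC")):
            F = fluxes[name]
            if F <= 0:
                continue
            a = (F / n_entry) * field_.weights
            p = -np.expm1(-a * dt / gamma)
            hits = np.nonzero(rng.random(n_entry) < p)[0]
            for i in hits:
                vox = int(field_.entry_voxels[i])
                if self.occupancy.can_place(kind, vox):
                    self.add_agent(kind, self.grid.unflat(vox))
                    recruited[kind] += 1
                    self.recruited_totals[kind] += 1
        return recruited

    # -- QSP synchronization ---------------------------------------------
    def _sync_qsp_from_census(self) -> None:
        counts = inverse_scale_abm_to_qsp(self.census, self.coupling.gamma)
        self.qsp_state = replace(self.qsp_state, **counts)

    def check_identity(self) -> None:
        """Assert the inverse-scaling identity: QSP tumor counts equal
        γ times the census, exactly."""
        counts = inverse_scale_abm_to_qsp(self.census, self.coupling.gamma)
        s = self.qsp_state
        for name, val in counts.items():
            if getattr(s, name) != val:
                raise AssertionError(
                    f"coupling identity broken for {name}: {getattr(s, name)} != {val}")

    # -- the step ---------------------------------------------------------
    def step(self, dt: float | None = None, audit: bool = False) -> None:
        """One coupled step of length dt (defaults to τ)."""
        if not self.coupling.initialized:
            raise RuntimeError("coupling not initialized")
        dt = self.coupling.tau if dt is None else dt
        # dose events are aligned to step boundaries
        self.qsp_state = apply_dose(self.qsp_state, self.dose, self.t,
                                    tol=dt / 2)
        env = self.mediator_environment()
        self._migration_pass(dt)
        self._reaction_pass(dt, env)
        self.update_recruitment_weights()
        self.recruit_cells(dt)
        self._sync_qsp_from_census()
        self.check_identity()
        self.qsp_state = advance_qsp(self.qsp_state, self.qsp_params, dt,
                                     frozen_tumor_cells=True)
        self.t += dt
        if audit:
            self.occupancy.audit()
        self._log_row()

    def run(self, duration: float, audit_every: int = 0,
            progress: bool = False) -> None:
        n = int(round(duration / self.coupling.tau))
        for i in range(n):
            self.step(audit=bool(audit_every) and (i % audit_every == 0))

    # -- output -----------------------------------------------------------
    def _log_row(self) -> None:
        c = self.census
        cd8 = c[TEFF] + c[TCYT] + c[TEXH]
        ratio = cd8 / c[TREG] if c[TREG] > 0 else float("nan")
        self.log_rows.append({
            "t_day": self.t, "C": self.qsp_state.C,
            "CSC": c[CSC], "PC": c[PC], "SC": c[SC],
            "Teff": c[TEFF], "Tcyt": c[TCYT], "Texh": c[TEXH],
            "Treg": c[TREG], "MDSC": c[MDSC],
            "T1_central": self.qsp_state.T1_central,
            "drug_central": self.qsp_state.drug_central,
            "cd8_foxp3_ratio": ratio,
        })

    def timeseries(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_rows)

    def snapshot(self) -> pd.DataFrame:
        """One row per agent: t_day, cell_id, kind, state, ix, iy, iz."""
        rows = [{
            "t_day": self.t, "cell_id": a.id, "kind": KIND_NAMES[a.kind],
            "state": a.divisions_done if a.kind == PC else 0,
            "ix": a.position[0], "iy": a.position[1], "iz": a.position[2],
        } for a in self.agents.values()]
        cols = ["t_day", "cell_id", "kind", "state", "ix", "iy", "iz"]
        return pd.DataFrame(rows, columns=cols)
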