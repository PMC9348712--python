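"""Reduced whole-patient QSP model: four compartments, anti-PD-1 PK/PD.

The model tracks cancer cells and immune cells in the tumor, T cells in the
central (blood) compartment and the tumor-draining lymph node (TDLN), three
soluble mediators treated as spatially uniform over the tumor (arginase-I,
CCL2, nitric oxide), and a two-compartment linear PK for an anti-PD-1
antibody.  It is a minimal mechanistic surrogate exposing exactly the
species the agent-based tumor couples to; a full externally-built model can
be supplied through the SBML import hook (:mod:`spqsp.sbml`) instead.

Functional forms:

* logistic cancer growth, killing by effector T cells saturating in the
  effector:target ratio and inhibited by NO, Arg-I and unbound PD-1
  (Hill factors in (0, 1]);
* TDLN priming driven by tumor antigen load, a single transit into blood,
  first-order extravasation into the tumor;
* Treg expansion activated by Arg-I and capped by a maximal intratumoral
  Treg density;
* MDSC recruitment with a CCL2-dependent component; mediator secretion
  proportional to the secreting population over the tumor volume;
* PD-1 occupancy is an algebraic Hill function of the central drug
  concentration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

log = logging.getLogger(__name__)

#: default cancer-cell volume: one 20 µm voxel = 8e-9 mL
CELL_VOLUME_ML = 8e-9


@dataclass
class QSPState:
    """Whole-patient state at time ``t`` (days).

    Cell species are counts; mediators are ng/mL; drug amounts are mg.
    """

    t: float = 0.0
    C: float = 1.0            # cancer cells in tumor
    T1: float = 0.0           # effector T cells in tumor
    Texh: float = 0.0         # exhausted/suppressed T cells in tumor
    T0: float = 0.0           # regulatory T cells in tumor
    MDSC: float = 0.0         # MDSCs in tumor
    T1_central: float = 0.0
    T0_central: float = 0.0
    T_LN: float = 0.0         # primed T cells in TDLN
    ArgI: float = 0.0
    CCL2: float = 0.0
    NO: float = 0.0
    drug_central: float = 0.0
    drug_peripheral: float = 0.0

    _VEC_FIELDS = ("C", "T1", "Texh", "T0", "MDSC", "T1_central", "T0_central",
                   "T_LN", "ArgI", "CCL2", "NO", "drug_central", "drug_peripheral")
    _COUNT_FIELDS = ("C", "T1", "Texh", "T0", "MDSC", "T1_central", "T0_central", "T_LN")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._VEC_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray) -> "QSPState":
        return cls(t, *map(float, y))

    def pd1_occupancy(self, params: "QSPParams") -> float:
        """Fraction of PD-1 receptors bound by drug, in [0, 1]."""
        conc = self.drug_central / params.V_central  # mg/mL
        return conc / (conc + params.KD_pd1)

    def validate(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise FloatingPointError(f"non-finite QSP state at t={self.t}: {self}")
        for f in self._VEC_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"negative state variable {f} at t={self.t}")


@dataclass
class QSPParams:
    """Rate constants of the reduced model (days, counts, mL, ng/mL, mg)."""

    # cancer
    kC1_growth: float = 0.01        # day^-1
    C_max: float = 5e8              # logistic capacity (cells)
    kC_T1: float = 1.43             # day^-1, killing rate by effector T cells
    K_kill: float = 1.0             # effector:target saturation offset
    # exhaustion / suppression
    kT1: float = 0.1                # day^-1, exhaustion via PD-L1
    kTreg: float = 0.0893           # day^-1, inhibition by Tregs
    K_Treg_inh: float = 1e4         # Treg count half-max for inhibition
    # death rates
    d_T1: float = 0.1
    d_Texh: float = 0.1
    d_T0: float = 0.1
    d_MDSC: float = 0.2
    d_T1_central: float = 0.01
    d_T0_central: float = 0.01
    # recruitment (central -> tumor), first order in central counts
    k_T1_rec: float = 0.1           # day^-1
    k_T0_rec: float = 0.05          # day^-1
    k_MDSC_base: float = 100.0      # cells/day
    k_MDSC_ccl2: float = 500.0      # cells/day at CCL2 saturation
    K_CCL2: float = 1.0             # ng/mL
    K_presence: float = 1e3         # cancer cells at half recruitment gating
    # TDLN priming and transit
    k_prime: float = 1e4            # cells/day at antigen saturation
    K_antigen: float = 1e6          # cancer cells at half priming
    k_LN_out: float = 0.5           # day^-1
    f_eff: float = 0.8              # fraction of primed cells becoming effectors
    # Treg expansion
    k_T0_exp: float = 0.2           # day^-1 at Arg-I saturation
    K_Arg_exp: float = 20.0         # ng/mL
    Treg_max: float = 2e6           # cell/mL, maximal intratumoral Treg density
    # mediators
    k_sec_Arg: float = 5e-5         # ng/day per MDSC
    k_sec_NO: float = 2e-5          # ng/day per MDSC
    k_sec_CCL2: float = 1e-9        # ng/day per cancer cell
    d_Arg: float = 5.0              # day^-1
    d_NO: float = 10.0
    d_CCL2: float = 2.0
    # killing inhibition half-max constants
    K_NO: float = 1.0               # ng/mL
    K_Arg_kill: float = 40.0        # ng/mL
    K_PD1: float = 0.5              # dimensionless, unbound-PD-1 half-max
    # PK (two-compartment, linear)
    k_cl: float = 0.0693            # day^-1 central clearance (~10 d half-life)
    k_cp: float = 0.3               # day^-1 central -> peripheral
    k_pc: float = 0.2               # day^-1 peripheral -> central
    V_central: float = 3100.0       # mL
    KD_pd1: float = 1e-6            # mg/mL (~1 µg/mL)
    # geometry
    cell_volume: float = CELL_VOLUME_ML  # mL per cancer cell

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"parameter {f.name} must be non-negative")
        if self.Treg_max <= 0:
            raise ValueError("Treg_max must be positive")

    def with_overrides(self, **kw) -> "QSPParams":
        return replace(self, **kw)


@dataclass
class DoseSchedule:
    """Repeated bolus dosing of the anti-PD-1 antibody into the central
    compartment (mg/kg body mass, every ``interval`` days from ``start``)."""

    dose_mg_per_kg: float = 3.0
    patient_mass: float = 70.0      # kg; mg/kg dosing needs a mass
    interval: float = 14.0          # days
    start: float = 0.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.enabled and self.interval <= 0:
            raise ValueError("dose interval must be positive")

    @property
    def dose_mg(self) -> float:
        return self.dose_mg_per_kg * self.patient_mass

    def is_dose_time(self, t: float, tol: float = 1e-6) -> bool:
        if not self.enabled or t < self.start - tol:
            return False
        k = round((t - self.start) / self.interval)
        return abs(t - (self.start + k * self.interval)) <= tol


def hill_inhibition(x: float, K: float) -> float:
    """Decreasing Hill factor K/(K + x) in (0, 1]."""
    return K / (K + x)


def killing_inhibition_factors(state: QSPState, params: QSPParams) -> tuple[float, float, float]:
    """(f_NO, f_ArgI, f_PD1): multiplicative inhibition of T cell killing.

    NO and Arg-I suppress killing; drug-bound PD-1 restores it (f_PD1 -> 1
    under full blockade).
    """
    f_no = hill_inhibition(state.NO, params.K_NO)
    f_arg = hill_inhibition(state.ArgI, params.K_Arg_kill)
    unbound = 1.0 - state.pd1_occupancy(params)
    f_pd1 = hill_inhibition(unbound, params.K_PD1)
    return f_no, f_arg, f_pd1


def tumor_volume(state: QSPState, cell_volume: float = CELL_VOLUME_ML) -> tuple[float, float]:
    """Tumor volume (mL) and equivalent spherical diameter (mm) from the
    cancer-cell count, assuming a spherical tumor of packed cells."""
    if cell_volume <= 0:
        raise ValueError("cell_volume must be positive")
    volume = state.C * cell_volume
    diameter_cm = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    return volume, 10.0 * diameter_cm


def recruitment_fluxes(state: QSPState, params: QSPParams) -> dict[str, float]:
    """Whole-tumor recruitment fluxes (cells/day) from blood into the tumor.

    These are the fluxes the spatial model spreads over its vascular entry
    points; they are gated by tumor presence so an empty tumor recruits
    nothing.
    """
    gate = state.C / (state.C + params.K_presence) if state.C > 0 else 0.0
    ccl2 = state.CCL2 / (state.CCL2 + params.K_CCL2) if state.CCL2 > 0 else 0.0
    return {
        "Teff": params.k_T1_rec * state.T1_central * gate,
        "Treg": params.k_T0_rec * state.T0_central * gate,
        "MDSC": (params.k_MDSC_base + params.k_MDSC_ccl2 * ccl2) * gate,
    }


def qsp_rhs(state: QSPState, params: QSPParams,
            frozen_tumor_cells: bool = False) -> np.ndarray:
    """Time derivative of the QSP state vector.

    With ``frozen_tumor_cells`` the derivatives of the five tumor cell
    species are zeroed: in the coupled model those species are owned by the
    agent-based tumor and enter here only as inputs (mediator secretion,
    antigen load, recruitment gating).
    """
    state.validate()
    p = params
    V_T = max(state.C, 1.0) * p.cell_volume  # mL

    f_no, f_arg, f_pd1 = killing_inhibition_factors(state, p)
    occ = state.pd1_occupancy(p)

    growth = p.kC1_growth * state.C * (1.0 - state.C / p.C_max)
    kill_sat = state.T1 / (state.T1 + state.C + p.K_kill) if state.T1 > 0 else 0.0
    killing = p.kC_T1 * state.C * kill_sat * f_no * f_arg * f_pd1

    exh_rate = (p.kT1 * (1.0 - occ)
                + p.kTreg * state.T0 / (state.T0 + p.K_Treg_inh))
    exhaustion = exh_rate * state.T1

    flux = recruitment_fluxes(state, p)

    treg_density = state.T0 / V_T
    expansion = (p.k_T0_exp * state.T0
                 * state.ArgI / (state.ArgI + p.K_Arg_exp)
                 * max(0.0, 1.0 - treg_density / p.Treg_max))

    dC = growth - killing
    dT1 = flux["Teff"] - p.d_T1 * state.T1 - exhaustion
    dTexh = exhaustion - p.d_Texh * state.Texh
    dT0 = flux["Treg"] + expansion - p.d_T0 * state.T0
    dMDSC = flux["MDSC"] - p.d_MDSC * state.MDSC

    priming = p.k_prime * state.C / (state.C + p.K_antigen)
    dT_LN = priming - p.k_LN_out * state.T_LN
    dT1c = (p.f_eff * p.k_LN_out * state.T_LN
            - (p.d_T1_central + p.k_T1_rec) * state.T1_central)
    dT0c = ((1.0 - p.f_eff) * p.k_LN_out * state.T_LN
            - (p.d_T0_central + p.k_T0_rec) * state.T0_central)

    dArg = p.k_sec_Arg * state.MDSC / V_T - p.d_Arg * state.ArgI
    dCCL2 = p.k_sec_CCL2 * state.C / V_T - p.d_CCL2 * state.CCL2
    dNO = p.k_sec_NO * state.MDSC / V_T - p.d_NO * state.NO

    dAc = -(p.k_cl + p.k_cp) * state.drug_central + p.k_pc * state.drug_peripheral
    dAp = p.k_cp * state.drug_central - p.k_pc * state.drug_peripheral

    if frozen_tumor_cells:
        dC = dT1 = dTexh = dT0 = dMDSC = 0.0

    return np.array([dC, dT1, dTexh, dT0, dMDSC, dT1c, dT0c, dT_LN,
                     dArg, dCCL2, dNO, dAc, dAp])


#: integrator tolerances; counts span many orders of magnitude
ATOL = 1e-9
RTOL = 1e-6


def advance_qsp(state: QSPState, params: QSPParams, dt: float,
                frozen_tumor_cells: bool = False) -> QSPState:
    """Integrate the model over ``dt`` days with a stiff-capable method.

    Tiny integrator undershoots below zero are clamped to zero (with a
    logged warning); anything worse is a genuine failure and raises.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate()
    y0 = state.to_vector()

    def rhs(t, y):
        s = QSPState.from_vector(t, np.maximum(y, 0.0))
        return qsp_rhs(s, params, frozen_tumor_cells=frozen_tumor_cells)

    sol = solve_ivp(rhs, (state.t, state.t + dt), y0, method="LSODA",
                    rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise RuntimeError(
            f"QSP integration failed at t={state.t}: {sol.message}; state={state}")
    y = sol.y[:, -1]
    undershoot = y < 0
    if np.any(undershoot):
        worst = float(y.min())
        if worst < -1e-6 * max(1.0, float(np.abs(y0).max())):
            raise RuntimeError(
                f"QSP integration produced negative state {worst} at t={state.t + dt}")
        log.warning("clamping small negative QSP values (min %.3e) at t=%.4f",
                    worst, state.t + dt)
        y = np.maximum(y, 0.0)
    return QSPState.from_vector(state.t + dt, y)


def apply_dose(state: QSPState, schedule: DoseSchedule, t: float,
               tol: float = 1e-6) -> QSPState:
    """Add one bolus to the central compartment if ``t`` is a dosing time."""
    if schedule.is_dose_time(t, tol):
        return replace(state, drug_central=state.drug_central + schedule.dose_mg)
    return state
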