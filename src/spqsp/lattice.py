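"""3D voxel lattice with occupancy rules, Moore neighborhoods and no-flux edges.

The tumor domain is a parallelepiped of cubic voxels (default edge 20 µm).
Each voxel holds at most one "large" occupant (a cancer cell of any subtype,
or an MDSC) and up to eight T cells; when a large occupant is present, at
most one T cell may share the voxel.  Cells interact only within their Moore
neighborhood (the 26 voxels at Chebyshev distance 1); neighborhoods are
clipped at the domain edges, which realizes no-flux boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# agent kind codes; "large" occupants (cancer cells, MDSCs) exclude one another
CSC, PC, SC, MDSC, TEFF, TCYT, TEXH, TREG = 1, 2, 3, 4, 5, 6, 7, 8

LARGE_KINDS = frozenset({CSC, PC, SC, MDSC})
CANCER_KINDS = frozenset({CSC, PC, SC})
TCELL_KINDS = frozenset({TEFF, TCYT, TEXH, TREG})

KIND_NAMES = {
    CSC: "CSC", PC: "PC", SC: "SC", MDSC: "MDSC",
    TEFF: "Teff", TCYT: "Tcyt", TEXH: "Texh", TREG: "Treg",
}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}

MAX_TCELLS_PER_VOXEL = 8
MAX_TCELLS_WITH_LARGE = 1

_MOORE_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the voxel lattice.

    nx, ny, nz: voxel counts along each axis; L: voxel edge length in µm.
    """

    nx: int
    ny: int
    nz: int
    L: float = 20.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.L <= 0:
            raise ValueError("voxel edge length must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def L_mm(self) -> float:
        return self.L * 1e-3

    def in_bounds(self, pos: tuple[int, int, int]) -> bool:
        x, y, z = pos
        return 0 <= x < self.nx and 0 <= y < self.ny and 0 <= z < self.nz

    def flat(self, pos: tuple[int, int, int]) -> int:
        x, y, z = pos
        return (x * self.ny + y) * self.nz + z

    def unflat(self, idx: int) -> tuple[int, int, int]:
        idx, z = divmod(idx, self.nz)
        x, y = divmod(idx, self.ny)
        return (x, y, z)


def neighbors(pos: tuple[int, int, int], grid: GridSpec) -> list[tuple[int, int, int]]:
    """Moore neighbors of ``pos`` (Chebyshev distance 1), clipped at the edges."""
    if not grid.in_bounds(pos):
        raise IndexError(f"voxel {pos} outside grid {grid.shape}")
    x, y, z = pos
    out = []
    for dx, dy, dz in _MOORE_OFFSETS:
        q = (x + dx, y + dy, z + dz)
        if grid.in_bounds(q):
            out.append(q)
    return out


class VoxelOccupancy:
    """Ledger of who occupies which voxel.

    Backed by flat integer buffers so the simulation loop can index it
    cheaply; numpy views (zero-copy) are exposed for raster analytics.
    """

    def __init__(self, grid: GridSpec):
        self.grid = grid
        n = grid.n_voxels
        self.large_kind = np.zeros(n, dtype=np.int8)    # 0 = empty
        self.large_id = np.full(n, -1, dtype=np.int64)
        self.tcell_count = np.zeros(n, dtype=np.int16)
        # per-kind T cell counters (needed for neighborhood interrogation)
        self.kind_count = {k: np.zeros(n, dtype=np.int16) for k in TCELL_KINDS}

    # -- queries ---------------------------------------------------------
    def can_place(self, kind: int, voxel: int) -> bool:
        """True iff adding one cell of ``kind`` keeps the occupancy invariants."""
        if kind in LARGE_KINDS:
            return self.large_kind[voxel] == 0 and self.tcell_count[voxel] <= MAX_TCELLS_WITH_LARGE
        # T cell
        if self.large_kind[voxel] != 0:
            return self.tcell_count[voxel] < MAX_TCELLS_WITH_LARGE
        return self.tcell_count[voxel] < MAX_TCELLS_PER_VOXEL

    # -- updates ---------------------------------------------------------
    def place(self, kind: int, voxel: int, agent_id: int) -> None:
        if not self.can_place(kind, voxel):
            raise RuntimeError(f"occupancy violation placing kind {kind} at voxel {voxel}")
        if kind in LARGE_KINDS:
            self.large_kind[voxel] = kind
            self.large_id[voxel] = agent_id
        else:
            self.tcell_count[voxel] += 1
            self.kind_count[kind][voxel] += 1

    def remove(self, kind: int, voxel: int, agent_id: int) -> None:
        if kind in LARGE_KINDS:
            if self.large_id[voxel] != agent_id:
                raise RuntimeError("ledger inconsistency: removing absent large occupant")
            self.large_kind[voxel] = 0
            self.large_id[voxel] = -1
        else:
            if self.kind_count[kind][voxel] <= 0:
                raise RuntimeError("ledger inconsistency: removing absent T cell")
            self.tcell_count[voxel] -= 1
            self.kind_count[kind][voxel] -= 1

    def retype_tcell(self, old_kind: int, new_kind: int, voxel: int) -> None:
        self.kind_count[old_kind][voxel] -= 1
        self.kind_count[new_kind][voxel] += 1

    def retype_large(self, new_kind: int, voxel: int) -> None:
        self.large_kind[voxel] = new_kind

    # -- audits ----------------------------------------------------------
    def audit(self) -> None:
        """Raise if any voxel violates the co-occupancy rules."""
        tc = self.tcell_count
        has_large = self.large_kind != 0
        if tc.max(initial=0) > MAX_TCELLS_PER_VOXEL:
            raise AssertionError("voxel exceeds 8 T cells")
        if np.any(tc[has_large] > MAX_TCELLS_WITH_LARGE):
            raise AssertionError("voxel with a large occupant holds >1 T cell")
        per_kind = sum(self.kind_count.values())
        if not np.array_equal(per_kind, tc):
            raise AssertionError("per-kind T cell counters disagree with totals")
        if np.any((self.large_id >= 0) != has_large):
            raise AssertionError("large-occupant id/kind buffers disagree")


def migration_probability(u: float, dt: float) -> float:
    """Probability that a cell with migration rate ``u`` (day^-1) attempts one
    move during a step of length ``dt`` (day): 1 - exp(-u*dt)."""
    if u < 0 or dt < 0:
        raise ValueError("migration rate and time step must be non-negative")
    return -np.expm1(-u * dt)


def move_offsets(grid: GridSpec) -> list[tuple[int, int, int]]:
    """Attemptable migration offsets: the Moore set of the grid's effective
    dimensionality (26, or the 8 in-plane offsets for a single-layer grid)."""
    if grid.nz == 1:
        return [o for o in _MOORE_OFFSETS if o[2] == 0]
    return list(_MOORE_OFFSETS)


def migration_step(agent, u: float, dt: float, occupancy: VoxelOccupancy,
                   rng: np.random.Generator,
                   offsets: list[tuple[int, int, int]] | None = None) -> bool:
    """Attempt one stochastic move of ``agent``; returns True if it moved.

    With probability 1 - exp(-u*dt) the agent attempts a jump along a
    uniformly chosen Moore direction; the attempt fails (the agent stays)
    if the target lies outside the grid (no-flux) or its occupancy rules
    forbid the move.  Failed attempts are not redirected: renormalizing
    over free neighbors would give interface cells a net outward drift and
    break the match between the migration rate and the continuum
    diffusivity.  The occupancy ledger is updated atomically.
    """
    if rng.random() >= migration_probability(u, dt):
        return False
    grid = occupancy.grid
    offs = offsets if offsets is not None else move_offsets(grid)
    dx, dy, dz = offs[int(rng.integers(len(offs)))]
    x, y, z = agent.position
    q = (x + dx, y + dy, z + dz)
    if not grid.in_bounds(q):
        return False
    target = grid.flat(q)
    if not occupancy.can_place(agent.kind, target):
        return False
    here = grid.flat(agent.position)
    occupancy.remove(agent.kind, here, agent.id)
    occupancy.place(agent.kind, target, agent.id)
    agent.position = q
    return True


def _pick_admissible(kind: int, candidates: list[int], occupancy: VoxelOccupancy,
                     rng: np.random.Generator) -> int | None:
    """Uniform draw over the admissible subset of ``candidates`` (or None).

    Implemented as rejection sampling without replacement, which is uniform
    over the admissible set without enumerating it when the first pick wins.
    """
    n = len(candidates)
    if n == 0:
        return None
    # lazy Fisher-Yates over a local copy
    cand = list(candidates)
    for i in range(n):
        j = i + int(rng.integers(n - i))
        cand[i], cand[j] = cand[j], cand[i]
        if occupancy.can_place(kind, cand[i]):
            return cand[i]
    return None


def lattice_diffusivity(u: float, dt: float, grid: GridSpec) -> float:
    """Continuum diffusivity (mm^2/day) matched to the migration rule.

    A mover jumps to a uniformly chosen Moore neighbor once per step with
    probability 1 - exp(-u*dt); the per-axis mean squared displacement of a
    jump is fâ‹…L^2 with f the fraction of neighbors shifting that axis
    (18/26 in 3D, 6/8 for a single-layer grid), so
    D = (1 - exp(-u dt)) * f * L^2 / (2 dt).
    """
    p = migration_probability(u, dt)
    f = 6.0 / 8.0 if grid.nz == 1 else 18.0 / 26.0
    L_mm = grid.L_mm
    return p * f * L_mm * L_mm / (2.0 * dt)
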