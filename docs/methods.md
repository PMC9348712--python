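# Methods

## Model structure

The package couples two representations of the same tumor:

* a deterministic compartment model of the patient (ODEs over cell counts,
  mediator concentrations and drug amounts), and
* a stochastic on-lattice agent model of the tumor microenvironment.

From initialization onward the lattice *owns* the five tumor cell species
(cancer cells, effector, exhausted and regulatory T cells, MDSCs): after
every coupling step of length τ the census times γ overwrites the
compartmental counts, and during the ODE advance the derivatives of those
five species are frozen at zero. The ODE system keeps evolving everything
the lattice does not represent — lymph-node priming, blood-compartment T
cells, the mediators Arg-I, CCL2 and NO (treated as uniform over the
tumor), and antibody PK with algebraic PD-1 occupancy
`occ = c/(c + K_D)` on the central drug concentration.

### Reduced compartment model

The whole-patient part is a deliberately small mechanistic surrogate, not
a reproduction of any published full-scale QSP model. Functional forms:

* cancer: logistic growth `k_growth·C·(1−C/C_max)` minus killing
  `k_kill·C·T1/(T1+C+K)·f_NO·f_ArgI·f_PD1`, each `f` a decreasing Hill
  factor `K/(K+x)`; the PD-1 factor takes `x = 1 − occ`, so blockade
  restores killing toward its ceiling;
* effector exhaustion at rate `k_T1·(1−occ) + k_Treg·T0/(T0+K)`;
* Treg expansion activated by Arg-I and capped by a maximal intratumoral
  density `Treg_max` (cell/mL, against the volume `C·v_cell`);
* MDSC recruitment with a CCL2-saturating component; mediator
  concentrations follow secretion/(tumor volume) minus first-order decay;
* lymph node: antigen-saturating priming `k_prime·C/(C+K_ag)`, single
  transit to blood, first-order extravasation into the tumor;
* PK: two linear compartments with central clearance.

Users with a full model can import it from SBML (Level 2/3 ODE core:
species, reactions with MathML kinetic laws, rate rules; events, function
definitions and algebraic rules are rejected explicitly). The importer is
self-contained; the coupling layer refuses to start until all five tumor
species are mapped to SBML identifiers.

Integration uses LSODA with `atol = 1e-9`, `rtol = 1e-6` (counts span many
orders of magnitude); sub-tolerance negative undershoots are clamped to
zero with a logged warning, anything worse raises.

### Lattice rules

Voxels are 20 µm cubes. Occupancy: at most one "large" occupant (cancer
cell or MDSC) per voxel, at most eight T cells, and at most one T cell
sharing a voxel with a large occupant. Every stochastic event converts a
propensity `a` (day⁻¹) to a per-step probability `1 − exp(−a·Δt)`.

Update order within a step: dosing (at step boundaries) → migration of all
agents (shuffled) → reactions (shuffled; neighborhood counts are computed
once from the post-migration grids and held fixed during the pass) →
recruitment → inverse scaling → ODE advance. Two runs with the same seed
are bitwise identical; the run RNG is a counter-based Philox generator
with per-subsystem substreams (init, migration, reactions, recruitment,
shuffling).

**Migration semantics.** A mover attempts a jump along a uniformly chosen
Moore direction (26 in 3D, the 8 in-plane directions on single-layer
grids) and simply fails when the target is out of bounds or blocked.
Failed attempts are *not* redirected to a free neighbor: renormalizing
over vacancies gives interface cells a net outward drift, which makes
invasion fronts travel far above the pulled-front speed and would
contradict the Fisher–KPP analysis used for the invasive-front cutoffs.
With attempt-based exclusion the collective diffusivity equals the
free-cell diffusivity, `D = (1−e^{−uΔt})·f·L²/(2Δt)` with `f = 18/26`
(3D) or `6/8` (planar) the fraction of directions displacing a given
axis (`lattice_diffusivity`). Division placement, by contrast, picks a
uniformly chosen *admissible* neighbor and aborts when the whole
neighborhood is blocked (contact inhibition).

**Division bookkeeping.** Both daughters of a progenitor division inherit
the incremented division count, so an unconstrained clone founded by one
progenitor with budget `d_max` terminates as exactly `2^d_max` senescent
cells — the combinatorial oracle used in the tests.

### Coupling and recruitment

Scaling is `⌊count/γ⌋` (QSP→lattice) and `γ × census` (lattice→QSP); the
effector and cytotoxic pools jointly map to the compartmental effector
count. Whole-tumor recruitment fluxes (cells/day) are read from the
compartment model at the start of each step, split evenly over the entry
voxels (a uniformly sampled fraction `rv_fraction` of the grid, one point
per voxel), weighted by a piecewise-linear bump of the local normalized
cancer density over the front band (floor 0.1, peak at the band center,
renormalized to mean 1), and converted to per-point Bernoulli draws with
`p = 1 − exp(−a·τ/γ)` — so the expected lattice influx times γ equals the
compartmental flux. Placements that violate occupancy are dropped.

In coarse-grained mode (γ ≫ 1, whole-tumor runs) migration rates are
multiplied by γ^(−1/3): a super-cell agent then moves as far per unit time
as the packet of cells it represents.

## Invasive-front analytics

The projected 2D cancer pattern is binned to a raster (pixel = voxel edge,
20 µm) and convolved with a Gaussian kernel. The bandwidth follows the
analytic rule `σ = |x|/√(2 ln(1/ε))` with `|x|` estimated as half the
largest nearest-neighbor spacing of the pattern and ε the outer density
cutoff (default 0.05 = C_min/C; below it, cell presence is treated as
zero). A two-scale variant (`kde2d_adaptive`) blends a 3σ-bandwidth
estimate in the dense core with the fine estimate near the front,
suppressing plateau speckle that would otherwise bias the max
normalization.

The inner cutoff comes from the traveling-wave profile of the Fisher–KPP
equation at the minimal speed `c = 2√(rD)`, solved by integrating away
from the saturated state along its unstable direction, with `(D, r)`
continuum-matched to the progenitor population; the cutoff is the
normalized density found `w_pathol` (default 1 mm, the conventional
pathology front width) behind the point where the wave equals ε. By
construction, segmenting a KPP-shaped front with these two cutoffs yields
a band of width `w_pathol`.

Width measurement (`mean_if_width`) takes, per azimuthal sector around the
cancer-density centroid, the largest radius inside the connected
super-level region of each cutoff that contains the center; detached
islands of stray cells beyond the continuous boundary are excluded (they
are islands, not the front). T cell profiles re-rank raster pixels by
descending cancer density (a monotone proxy for core-to-tissue distance),
bin them equal-count, and average the T cell kernel density (divided by
L², multiplied by the augmentation factor λ, default 6), with percentile
bootstrap 95% CIs from 1000 resamples; the along-front profile averages
over front-labelled pixels per azimuthal sector, reporting empty sectors
as missing.

## Parameter choices

Dimensionless regime parameters (`R`, `k`, `d_max`, rate ratios, `Treg_max`,
growth rates 0.005/0.01/0.015 per day) pin the scenario families; absolute
division and migration rates are free and were fixed once as desk-scale
defaults:

* slice scenarios: progenitor division rate matched to the compartmental
  growth rate (`r_p = k_growth`), `u_p = 4`/day, τ = 0.25 day. This puts
  the slow-growth front decay length `ℓ = √(D/r) ≈ 0.28 mm`, so the 1 mm
  band spans ~3.6 ℓ and its inner cutoff (ρ ≈ 0.32) sits on the steep,
  well-conditioned part of the profile, away from both the noisy density
  plateau and the stray-cell floor. CSC rates follow from R with CSC
  migration dominant in the slow regime (u_st = 8/day) and CSC
  proliferation dominant in the fast one;
* morphology scenarios: `r_p = 0.5`/day, `u_p = 10`/day on a 60³ grid for
  16 days (full-size 150³/16-month grids sit behind a flag);
* dosing: 3 mg/kg every 14 days; the body mass default is 70 kg (mg/kg
  dosing needs one);
* cancer-cell volume 8×10⁻⁹ mL (one voxel), used for the spherical
  equivalent diameter and density conversions.

Slab runs are seeded with a *developed front*: voxel-wise Bernoulli
occupancy equal to the KPP wave profile around a 0.9 mm core in a
260×260×1 slab (5.2×5.2 mm). At desk-scale division rates a front cannot
be grown from scratch in reasonable wall time (profile relaxation takes
~1/r ≈ 200 days of simulated time), so the run starts from the asymptotic
shape and the dynamics perturb it. The 30-day duration gives the immune
infiltrate about three turnover times (death rate 0.1/day) and the front
measurable advance while keeping the stray stem-cell fringe of the R ≪ 1
regime clear of the no-flux boundary.

The self-consistency scenario (γ = 1, linear rules only) uses τ = 0.05 day
because the per-step coupling biases — synchronous-update branching
deficit, left-endpoint sampling of the decaying blood-compartment flux,
end-of-step recruit ages — are O(τ) and at τ = 0.25 their sum is
comparable to the 3-standard-error band of a 100-replicate comparison.

## What the synthetic scenarios do and do not show

The generators emulate: contact-inhibited growth from single founders or
developed fronts, front-biased extravasation, mediator-coupled
suppression, and anti-PD-1 PK/PD — enough to exercise every coupling and
analysis path end to end. They do not emulate vasculature or angiogenesis,
ECM, macrophages/fibroblasts, antigen presentation beyond a saturating
priming term, spatial mediator gradients, or clinically calibrated
virtual-patient variability. Passing tests therefore demonstrate internal
consistency of the hybrid scheme and its analytics at desk scale, not
clinical predictive power.

## Numerical notes and limitations

* Stochastic invasion fronts at one cell per site run a few percent below
  `2√(rD)` (finite-occupancy correction); the front-speed check allows
  20%.
* The measured invasive-front width on the slow-growth slab runs ~10%
  above `w_pathol`: the front-biased infiltrate erodes the inner contour
  inward while stray stem cells extend the outskirts. Both effects grow
  with run length; see the duration rationale above.
* Face counting overestimates oblique voxel surfaces by 3/2 on average;
  the sphericity index applies that correction and clamps at 1. Shape
  indices are descriptive, not calibrated to pathology scores.
* `mean_if_width` requires at least one azimuthal sector crossing both
  cutoffs and raises otherwise; profiles with no T cells return a zero
  profile flagged degenerate rather than fabricating CIs.
* The SBML importer evaluates kinetic laws per reaction in pure Python; it
  is meant for models of tens of species, not thousands.
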