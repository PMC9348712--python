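"""Analytic invasive-front (IF) definition and T cell infiltration profiles.

A projected 2D point pattern of cancer cells is turned into a smooth,
max-normalized density ρ with a Gaussian kernel.  Two density cutoffs
partition space into central tumor (CT, ρ ≥ ρ_cutoff_max), invasive front
(IF) and normal tissue (N, ρ < ρ_cutoff_min):

* the outer cutoff ε = C_min/C marks where cell presence is treated as
  zero, and fixes the kernel bandwidth analytically through
  σ = |x| / sqrt(2 ln(1/ε)) with |x| half the largest observable gap
  between cells far from the core;
* the inner cutoff is the normalized density found a pathologist's front
  width w_pathol behind the outer boundary on the traveling-wave profile of
  the Fisher–KPP equation, the continuum limit of proliferating, migrating
  cancer cells, so that the segmented band is approximately w_pathol wide.

T cell infiltration is summarized as a density-distance profile
perpendicular to the front (pixels ranked by descending cancer density) and
as an azimuthal profile along the front band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.integrate import solve_ivp
from scipy.spatial import cKDTree

# region labels
N_LABEL, IF_LABEL, CT_LABEL = 0, 1, 2


@dataclass(frozen=True)
class RasterSpec:
    """Regular 2D raster: origin (mm), pixel count, pixel size (mm).

    Default pixel size 0.02 mm matches the lattice voxel edge; no finer
    spatial information exists in the simulation output.
    """

    x0: float
    y0: float
    nx: int
    ny: int
    pixel_mm: float = 0.02

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.pixel_mm
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.pixel_mm
        return x, y

    @classmethod
    def cover(cls, points: np.ndarray, pixel_mm: float = 0.02,
              pad_mm: float = 0.0) -> "RasterSpec":
        x0 = float(points[:, 0].min()) - pad_mm
        y0 = float(points[:, 1].min()) - pad_mm
        nx = int(math.ceil((points[:, 0].max() + pad_mm - x0) / pixel_mm)) + 1
        ny = int(math.ceil((points[:, 1].max() + pad_mm - y0) / pixel_mm)) + 1
        return cls(x0, y0, nx, ny, pixel_mm)


@dataclass
class IFSegmentation:
    """Per-pixel CT/IF/N labels plus the parameters that produced them."""

    labels: np.ndarray                 # int array over the raster, N/IF/CT
    raster: RasterSpec
    sigma: float                       # KDE bandwidth (mm)
    rho_cutoff_min: float
    rho_cutoff_max: float
    w_pathol: float | None = None      # target front width (mm), if used
    density: np.ndarray | None = None  # the normalized density segmented

    def __post_init__(self) -> None:
        # equal cutoffs are allowed: they produce a zero-measure front band
        if not 0.0 < self.rho_cutoff_min <= self.rho_cutoff_max <= 1.0:
            raise ValueError("need 0 < rho_cutoff_min <= rho_cutoff_max <= 1")


@dataclass
class DensityProfile:
    """Binned mean density (cells/mm^2) with bootstrap 95% CI bounds."""

    abscissa: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    augmentation: float = 1.0
    degenerate: bool = False    # no cells: zero profile, CIs meaningless


def kde2d(points: np.ndarray, sigma: float, raster: RasterSpec,
          normalize: bool = True) -> np.ndarray:
    """Gaussian kernel density of a 2D point pattern on a raster.

    Points are binned to pixels and convolved with an isotropic Gaussian of
    standard deviation ``sigma`` (mm).  Without normalization the raster
    integrates to the point count (density per mm^2, up to quadrature
    error); with it, the maximum is scaled to 1 (the ρ convention).
    An empty pattern yields an all-zero raster.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    counts = np.zeros(raster.shape)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size:
        ix = np.floor((points[:, 0] - raster.x0) / raster.pixel_mm).astype(int)
        iy = np.floor((points[:, 1] - raster.y0) / raster.pixel_mm).astype(int)
        keep = (ix >= 0) & (ix < raster.nx) & (iy >= 0) & (iy < raster.ny)
        np.add.at(counts, (ix[keep], iy[keep]), 1.0)
    dens = ndimage.gaussian_filter(counts, sigma=sigma / raster.pixel_mm,
                                   mode="constant", truncate=6.0)
    dens /= raster.pixel_mm ** 2
    if normalize:
        m = dens.max()
        return dens / m if m > 0 else dens
    return dens


def kde2d_adaptive(points: np.ndarray, sigma: float, raster: RasterSpec,
                   core_factor: float = 3.0,
                   blend_band: tuple[float, float] = (0.2, 0.6)) -> np.ndarray:
    """Two-scale KDE: wide kernels near the dense core, narrow at the front.

    The coarse estimate (bandwidth ``core_factor``·σ) smooths away the
    speckle of the density plateau; the fine estimate keeps the front
    gradients sharp.  The two are blended linearly by the coarse density
    over ``blend_band`` and the result is max-normalized.
    """
    fine = kde2d(points, sigma, raster, normalize=False)
    coarse = kde2d(points, core_factor * sigma, raster, normalize=False)
    m = coarse.max()
    cn = coarse / m if m > 0 else coarse
    lo, hi = blend_band
    b = np.clip((cn - lo) / (hi - lo), 0.0, 1.0)
    dens = b * coarse + (1.0 - b) * fine
    m = dens.max()
    return dens / m if m > 0 else dens


def estimate_sigma(x_half: float, epsilon: float) -> tuple[float, float]:
    """Analytic KDE bandwidth from the outer-boundary condition.

    A single kernel evaluated a distance |x| from its center must fall to
    ε of its peak: σ = |x| / sqrt(2 ln(1/ε)).  Returns (σ, ρ_cutoff_min=ε).
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie strictly between 0 and 1")
    if x_half <= 0:
        raise ValueError("x_half must be positive")
    sigma = x_half / math.sqrt(2.0 * math.log(1.0 / epsilon))
    return sigma, epsilon


def estimate_x_half(points: np.ndarray, quantile: float = 1.0) -> float:
    """Half of the largest nearest-neighbor spacing of the pattern.

    Cells far from the core dominate the largest spacings, which is the
    observable the bandwidth rule asks for; ``quantile`` < 1 discards the
    most extreme gaps.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    nn = d[:, 1]
    return 0.5 * float(np.quantile(nn, quantile))


def kpp_wave_profile(D: float, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Traveling-wave profile of the Fisher–KPP equation at the minimal
    speed c = 2·sqrt(rD): returns (z, U) with U decreasing from 1 to ~0.

    Solves D U'' + c U' + r U(1-U) = 0 by integrating away from the
    saturated state along its unstable direction.
    """
    if D <= 0 or r <= 0:
        raise ValueError("D and r must be positive")
    c = 2.0 * math.sqrt(r * D)
    lam = (-c + math.sqrt(c * c + 4.0 * r * D)) / (2.0 * D)
    ell = math.sqrt(D / r)
    v0 = 1e-8

    def rhs(z, y):
        U, V = y
        return [V, (-c * V - r * U * (1.0 - U)) / D]

    def tail(z, y):
        return y[0] - 1e-6
    tail.terminal = True
    tail.direction = -1

    sol = solve_ivp(rhs, (0.0, 200.0 * ell), [1.0 - v0, -lam * v0],
                    rtol=1e-10, atol=1e-14, max_step=ell / 5.0, events=tail,
                    dense_output=True)
    if not sol.success or len(sol.t_events[0]) == 0:
        raise RuntimeError("KPP wave solve did not converge")
    z = np.linspace(0.0, float(sol.t_events[0][0]), 8000)
    U = np.clip(sol.sol(z)[0], 0.0, 1.0)
    # anchor the (translation-invariant) wave at U = 0.5 -> z = 0 and trim
    # the long approach to the saturated state to a few decay lengths
    z_half = float(np.interp(-0.5, -U, z))
    z = z - z_half
    keep = z >= -20.0 * ell
    return z[keep], U[keep]


def rho_max_if(w_pathol: float, D: float, r: float,
               rho_cutoff_min: float) -> float:
    """Inner-boundary density cutoff for a front band of width ``w_pathol``.

    On the KPP traveling-wave profile, locate the outer boundary (where the
    normalized density equals ``rho_cutoff_min``) and return the density a
    distance ``w_pathol`` (mm) behind it.  Degenerate width returns the
    outer cutoff itself; a band wider than the whole wave saturates at 1.
    """
    if w_pathol < 0:
        raise ValueError("w_pathol must be non-negative")
    if not 0.0 < rho_cutoff_min < 1.0:
        raise ValueError("rho_cutoff_min must be in (0, 1)")
    if w_pathol == 0.0:
        return rho_cutoff_min
    z, U = kpp_wave_profile(D, r)
    z_eps = float(np.interp(rho_cutoff_min, U[::-1], z[::-1]))
    z_in = z_eps - w_pathol
    if z_in <= z[0]:
        return 1.0
    return float(np.interp(z_in, z, U))


def segment_regions(density: np.ndarray, rho_cutoff_min: float,
                    rho_cutoff_max: float, raster: RasterSpec | None = None,
                    sigma: float = float("nan"),
                    w_pathol: float | None = None) -> IFSegmentation:
    """Label every raster point: N below the outer cutoff, CT at or above
    the inner cutoff, IF in between (empty iff the cutoffs coincide)."""
    labels = np.full(density.shape, N_LABEL, dtype=np.int8)
    labels[density >= rho_cutoff_min] = IF_LABEL
    labels[density >= rho_cutoff_max] = CT_LABEL
    if raster is None:
        raster = RasterSpec(0.0, 0.0, *density.shape)
    return IFSegmentation(labels=labels, raster=raster, sigma=sigma,
                          rho_cutoff_min=rho_cutoff_min,
                          rho_cutoff_max=rho_cutoff_max, w_pathol=w_pathol,
                          density=density)


def density_centroid(density: np.ndarray, raster: RasterSpec) -> tuple[float, float]:
    """Density-weighted centroid (mm); the tumor center for radial work."""
    total = density.sum()
    if total <= 0:
        raise ValueError("empty density raster has no centroid")
    xc, yc = raster.centers()
    cx = float((density.sum(axis=1) @ xc) / total)
    cy = float((density.sum(axis=0) @ yc) / total)
    return cx, cy


def _main_component(mask: np.ndarray, center_px: tuple[int, int]) -> np.ndarray:
    """Connected component of ``mask`` containing (or nearest to) the center.

    Isolated cells and small aggregates outside the continuous boundary
    form islands that do not belong to the tumor region proper.
    """
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    lab = labels[center_px]
    if lab == 0:
        # center off the set: take the largest component
        lab = int(np.argmax(np.bincount(labels[labels > 0]))) if mask.any() else 0
    return labels == lab


def mean_if_width(density: np.ndarray, raster: RasterSpec,
                  rho_cutoff_min: float, rho_cutoff_max: float,
                  n_azimuth: int = 36,
                  center: tuple[float, float] | None = None) -> tuple[float, np.ndarray]:
    """Mean radial width of the front band over azimuthal sectors.

    The outer (inner) boundary is taken on the connected super-level region
    of the outer (inner) cutoff that contains the tumor center — detached
    islands of stray cells beyond the continuous boundary are excluded.
    Along each ray the boundary radius is the largest radius still inside
    the region; the width is the difference.  Rays that cross neither
    region are reported NaN and excluded from the mean.
    """
    if center is None:
        center = density_centroid(density, raster)
    cx, cy = center
    cpx = (int(round((cx - raster.x0) / raster.pixel_mm - 0.5)),
           int(round((cy - raster.y0) / raster.pixel_mm - 0.5)))
    outer_region = _main_component(density >= rho_cutoff_min, cpx)
    inner_region = _main_component(density >= rho_cutoff_max, cpx)
    xg, yg = raster.centers()
    rmax = max(xg[-1] - cx, cx - xg[0], yg[-1] - cy, cy - yg[0])
    rr = np.arange(0.0, rmax, raster.pixel_mm / 2.0)
    widths = np.full(n_azimuth, np.nan)
    for j in range(n_azimuth):
        th = 2.0 * math.pi * (j + 0.5) / n_azimuth
        px = (cx + rr * math.cos(th) - raster.x0) / raster.pixel_mm - 0.5
        py = (cy + rr * math.sin(th) - raster.y0) / raster.pixel_mm - 0.5
        prof_out = ndimage.map_coordinates(outer_region.astype(np.float32),
                                           [px, py], order=0, mode="constant")
        prof_in = ndimage.map_coordinates(inner_region.astype(np.float32),
                                          [px, py], order=0, mode="constant")
        above_out = np.nonzero(prof_out > 0)[0]
        above_in = np.nonzero(prof_in > 0)[0]
        if len(above_out) == 0 or len(above_in) == 0:
            continue
        widths[j] = rr[above_out[-1]] - rr[above_in[-1]]
    valid = widths[np.isfinite(widths)]
    if len(valid) == 0:
        raise ValueError("no azimuthal sector crosses both cutoffs")
    return float(valid.mean()), widths


def _bootstrap_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator,
                  alpha: float = 0.05) -> tuple[float, float]:
    idx = rng.integers(len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return (float(np.quantile(means, alpha / 2)),
            float(np.quantile(means, 1 - alpha / 2)))


def density_distance_profile(tcell_points: np.ndarray, cancer_density: np.ndarray,
                             segmentation: IFSegmentation, lam: float = 6.0,
                             L: float | None = None, n_bins: int = 40,
                             tcell_sigma: float | None = None,
                             n_boot: int = 1000,
                             rng: np.random.Generator | None = None) -> DensityProfile:
    """T cell density profile perpendicular to the front.

    Raster pixels are ranked by descending cancer density (the monotone
    proxy for core-to-tissue distance); T cell KDE values are reordered the
    same way, binned into ``n_bins`` equal-count bins and averaged, with
    percentile bootstrap 95% CIs.  Output densities are per mm^2 (the raw
    kernel output over L^2) times the augmentation factor λ.  The abscissa
    is the mean radial distance of each bin from the tumor centroid.
    """
    rng = rng or np.random.default_rng(0)
    raster = segmentation.raster
    tcell_points = np.atleast_2d(np.asarray(tcell_points, dtype=float))
    empty = tcell_points.size == 0
    sig = tcell_sigma or segmentation.sigma
    if empty:
        tdens = np.zeros(raster.shape)
    else:
        # counts-per-pixel kernel output; the L^2 division makes it per mm^2
        tdens = kde2d(tcell_points, sig, raster, normalize=False)
        tdens *= raster.pixel_mm ** 2
    Ldim = raster.pixel_mm if L is None else L
    tdens = tdens / (Ldim ** 2) * lam

    cx, cy = density_centroid(cancer_density, raster)
    xg, yg = raster.centers()
    rad = np.sqrt((xg[:, None] - cx) ** 2 + (yg[None, :] - cy) ** 2)

    order = np.argsort(-cancer_density, axis=None, kind="stable")
    tvals = tdens.ravel()[order]
    rvals = rad.ravel()[order]
    bins = np.array_split(np.arange(len(order)), n_bins)
    mean = np.array([tvals[b].mean() for b in bins])
    absc = np.array([rvals[b].mean() for b in bins])
    if empty:
        lo = hi = np.zeros_like(mean)
        return DensityProfile(absc, mean, lo, hi, lam, degenerate=True)
    ci = [_bootstrap_ci(tvals[b], n_boot, rng) for b in bins]
    lo = np.array([c[0] for c in ci])
    hi = np.array([c[1] for c in ci])
    return DensityProfile(absc, mean, lo, hi, lam)


def profile_along_if(tcell_points: np.ndarray, segmentation: IFSegmentation,
                     n_azimuth: int = 24, lam: float = 6.0,
                     L: float | None = None, tcell_sigma: float | None = None,
                     n_boot: int = 1000,
                     rng: np.random.Generator | None = None) -> DensityProfile:
    """Mean T cell density over front-labelled pixels per azimuthal sector.

    Sectors whose IF band is empty are reported as NaN (missing, not zero).
    The tumor center is the cancer-density centroid.
    """
    if not np.any(segmentation.labels == IF_LABEL):
        raise ValueError("segmentation has an empty front band")
    rng = rng or np.random.default_rng(0)
    raster = segmentation.raster
    tcell_points = np.atleast_2d(np.asarray(tcell_points, dtype=float))
    sig = tcell_sigma or segmentation.sigma
    if tcell_points.size == 0:
        tdens = np.zeros(raster.shape)
    else:
        tdens = kde2d(tcell_points, sig, raster, normalize=False)
        tdens *= raster.pixel_mm ** 2
    Ldim = raster.pixel_mm if L is None else L
    tdens = tdens / (Ldim ** 2) * lam

    cx, cy = density_centroid(segmentation.density
                              if segmentation.density is not None
                              else (segmentation.labels == CT_LABEL).astype(float),
                              raster)
    xg, yg = raster.centers()
    theta = np.arctan2(yg[None, :] - cy, xg[:, None] - cx)
    sector = np.floor((theta + math.pi) / (2 * math.pi) * n_azimuth).astype(int)
    sector = np.clip(sector, 0, n_azimuth - 1)

    absc = (np.arange(n_azimuth) + 0.5) * 2 * math.pi / n_azimuth - math.pi
    mean = np.full(n_azimuth, np.nan)
    lo = np.full(n_azimuth, np.nan)
    hi = np.full(n_azimuth, np.nan)
    in_if = segmentation.labels == IF_LABEL
    for j in range(n_azimuth):
        mask = in_if & (sector == j)
        if not mask.any():
            continue
        vals = tdens[mask]
        mean[j] = vals.mean()
        lo[j], hi[j] = _bootstrap_ci(vals, n_boot, rng)
    return DensityProfile(absc, mean, lo, hi, lam)
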