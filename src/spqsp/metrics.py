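"""Whole-tumor characterization: regime numbers, hotspots, shape, time series."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .invasive_front import RasterSpec, kde2d


@dataclass(frozen=True)
class RegimeDescriptor:
    """Dimensionless parameters governing tumor morphology.

    R = (r_st * u_p) / (r_p * u_st) compares stem-cell proliferation and
    progenitor migration against progenitor proliferation and stem-cell
    migration; together with the asymmetric-division probability k and the
    progenitor division budget d_max it selects the growth regime
    (regular/irregular shape, dense/sparse core, fingering).
    """

    R: float
    k: float
    d_max: int

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")


def compute_R(r_st: float, u_p: float, r_p: float, u_st: float) -> float:
    """The morphology ratio R = (r_st * u_p) / (r_p * u_st)."""
    if min(r_st, u_p, r_p, u_st) <= 0:
        raise ZeroDivisionError("all four rates must be positive")
    return (r_st * u_p) / (r_p * u_st)


def hotspot_map(points: np.ndarray, bandwidth: float,
                threshold_quantile: float = 0.95,
                raster: RasterSpec | None = None) -> pd.DataFrame:
    """Local density maxima ('hotspots') of a 2D point pattern.

    Returns a table (x_mm, y_mm, density) of local maxima of the Gaussian
    KDE that exceed the given quantile of the density evaluated at the
    points themselves (so sparse background noise does not spawn spots).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return pd.DataFrame(columns=["x_mm", "y_mm", "density"])
    if raster is None:
        raster = RasterSpec.cover(points, pad_mm=3 * bandwidth)
    dens = kde2d(points, bandwidth, raster, normalize=False)
    footprint = max(3, int(round(2 * bandwidth / raster.pixel_mm)) | 1)
    local_max = dens == ndimage.maximum_filter(dens, size=footprint,
                                               mode="constant")
    ix = np.clip(((points[:, 0] - raster.x0) / raster.pixel_mm).astype(int),
                 0, raster.nx - 1)
    iy = np.clip(((points[:, 1] - raster.y0) / raster.pixel_mm).astype(int),
                 0, raster.ny - 1)
    thr = np.quantile(dens[ix, iy], threshold_quantile)
    ix, iy = np.nonzero(local_max & (dens >= thr) & (dens > 0))
    xg, yg = raster.centers()
    out = pd.DataFrame({"x_mm": xg[ix], "y_mm": yg[iy],
                        "density": dens[ix, iy]})
    return out.sort_values("density", ascending=False).reset_index(drop=True)


def timeseries_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Counts and the CD8+/FoxP3+ ratio versus time from a run log.

    CD8+ T cells are the sum of effector, cytotoxic and exhausted cells;
    the ratio CD8/Treg is reported as NaN (undefined) when no Tregs are
    present, never as infinity.
    """
    if log.empty:
        raise ValueError("empty run log")
    out = log.copy()
    out["CD8"] = out["Teff"] + out["Tcyt"] + out["Texh"]
    treg = out["Treg"].to_numpy(dtype=float)
    cd8 = out["CD8"].to_numpy(dtype=float)
    ratio = np.full(len(out), np.nan)
    nz = treg > 0
    ratio[nz] = cd8[nz] / treg[nz]
    out["cd8_foxp3_ratio"] = ratio
    return out


def _boundary_faces(mask: np.ndarray) -> int:
    """Exposed voxel faces of a 3D boolean mask (6-face counting)."""
    n = int(mask.sum())
    shared = 0
    for axis in range(3):
        a = np.swapaxes(mask, 0, axis)
        shared += int(np.count_nonzero(a[1:] & a[:-1]))
    return 6 * n - 2 * shared


def shape_descriptors(mask: np.ndarray, L_mm: float = 0.02) -> dict[str, float]:
    """Shape summary of a 3D cancer occupancy mask.

    sphericity: surface of the equal-volume sphere over the voxel-face
    boundary surface (1 for a perfect ball, smaller for rough shapes);
    clusters: 26-connected components; fingering: fraction of boundary
    voxels relative to that of a continuum ball of equal volume (values
    well above 1 indicate fingering or fragmentation).  Descriptive
    indices, not calibrated against pathology scores.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty cancer mask")
    volume = n * L_mm ** 3
    faces = _boundary_faces(mask)
    # face counting overestimates the area of oblique surfaces by 3/2 on
    # average (staircase effect); correct so a digital ball scores ~1
    surface = faces * L_mm ** 2 / 1.5
    sphere_surface = math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0)
    labels, n_clusters = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    # boundary voxels: at least one empty 6-neighbor
    interior = ndimage.binary_erosion(mask)
    n_boundary = n - int(interior.sum())
    radius_vox = (3.0 * n / (4.0 * math.pi)) ** (1.0 / 3.0)
    sphere_boundary_frac = min(1.0, 3.0 / radius_vox)
    return {
        "sphericity": min(1.0, sphere_surface / surface),
        "clusters": float(n_clusters),
        "fingering": (n_boundary / n) / sphere_boundary_frac,
    }
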