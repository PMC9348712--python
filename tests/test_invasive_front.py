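"""KDE, bandwidth rule, KPP cutoff, segmentation and infiltration profiles."""

import math

import numpy as np
import pytest

from spqsp.invasive_front import (CT_LABEL, IF_LABEL, N_LABEL, RasterSpec,
                                  density_centroid, density_distance_profile,
                                  estimate_sigma, estimate_x_half, kde2d,
                                  kde2d_adaptive, kpp_wave_profile,
                                  mean_if_width, profile_along_if, rho_max_if,
                                  segment_regions)
from spqsp.scenarios import synthetic_radial_tumor


def raster(n=101, px=0.02):
    return RasterSpec(0.0, 0.0, n, n, px)


class TestKDE:
    def test_single_point_peak_normalized_to_one(self):
        r = raster()
        dens = kde2d(np.array([[1.0, 1.0]]), 0.1, r)
        assert dens.max() == pytest.approx(1.0)
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(r.centers()[0][i] - 1.0) <= r.pixel_mm
        assert abs(r.centers()[1][j] - 1.0) <= r.pixel_mm

    def test_two_distant_points_symmetric_peaks(self):
        dens = kde2d(np.array([[0.5, 0.5], [1.5, 1.5]]), 0.05, raster())
        assert dens.max() == pytest.approx(1.0)
        assert (dens > 0.99).sum() >= 2

    def test_value_at_distance_sigma(self):
        sigma = 0.1
        r = RasterSpec(-1.0, -1.0, 201, 201, 0.01)
        dens = kde2d(np.array([[0.0, 0.0]]), sigma, r)
        xg, yg = r.centers()
        i0 = np.argmin(np.abs(xg))
        j0 = np.argmin(np.abs(yg))
        js = np.argmin(np.abs(yg - sigma))
        ratio = dens[i0, js] / dens[i0, j0]
        assert ratio == pytest.approx(math.exp(-0.5), rel=0.02)

    def test_mass_integrates_to_point_count(self):
        pts = np.array([[1.0, 1.0], [0.8, 1.2], [1.2, 0.9]])
        r = raster(151)
        dens = kde2d(pts, 0.05, r, normalize=False)
        mass = dens.sum() * r.pixel_mm ** 2
        assert mass == pytest.approx(len(pts), rel=1e-3)

    def test_empty_pattern_all_zero(self):
        dens = kde2d(np.empty((0, 2)), 0.1, raster())
        assert not dens.any()

    def test_adaptive_blend_preserves_normalization(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(1.0, 0.2, size=(400, 2))
        dens = kde2d_adaptive(pts, 0.03, raster())
        assert dens.max() == pytest.approx(1.0)
        assert dens.min() >= 0.0


class TestSigmaRule:
    def test_eps_exp_minus_two_gives_half_x(self):
        sigma, rho = estimate_sigma(0.4, math.exp(-2.0))
        assert sigma == pytest.approx(0.2, rel=1e-14)
        assert rho == math.exp(-2.0)

    def test_eps_exp_minus_half_gives_x(self):
        sigma, _ = estimate_sigma(0.3, math.exp(-0.5))
        assert sigma == pytest.approx(0.3, rel=1e-14)

    def test_numeric_example(self):
        sigma, _ = estimate_sigma(0.1, 0.01)
        assert sigma == pytest.approx(0.03295, abs=2e-5)

    def test_kernel_round_trip_identity(self):
        """A single kernel evaluated at |x| with the returned sigma falls
        to exactly eps of its peak."""
        x_half, eps = 0.23, 0.037
        sigma, _ = estimate_sigma(x_half, eps)
        assert math.exp(-x_half ** 2 / (2 * sigma ** 2)) == pytest.approx(eps, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_sigma(0.1, 1.5)
        with pytest.raises(ValueError):
            estimate_sigma(-1.0, 0.1)

    def test_x_half_from_pattern(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 3.0]])
        # largest nearest-neighbor spacing is 3.0
        assert estimate_x_half(pts) == pytest.approx(1.5)


class TestKPPCutoff:
    def test_degenerate_width_returns_outer_cutoff(self):
        assert rho_max_if(0.0, 1e-3, 0.01, 0.05) == 0.05

    def test_monotone_in_width(self):
        vals = [rho_max_if(w, 4e-4, 0.005, 0.05) for w in (0.2, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0.05 < v <= 1.0 for v in vals)

    def test_wave_profile_shape(self):
        z, U = kpp_wave_profile(4e-4, 0.005)
        assert U[0] > 0.999
        assert U[-1] < 1e-3
        assert np.all(np.diff(U) <= 1e-12)      # monotone decreasing
        assert np.interp(0.0, z, U) == pytest.approx(0.5, abs=1e-3)

    def test_band_width_consistency_on_exact_profile(self):
        """Segmenting the analytic wave profile itself recovers the target
        width: the distance between the cutoff levels equals w_pathol."""
        D, r, eps, w = 4e-4, 0.005, 0.05, 1.0
        z, U = kpp_wave_profile(D, r)
        rho_max = rho_max_if(w, D, r, eps)
        z_out = np.interp(eps, U[::-1], z[::-1])
        z_in = np.interp(rho_max, U[::-1], z[::-1])
        assert z_out - z_in == pytest.approx(w, rel=1e-3)


class TestSegmentation:
    def test_uniform_zero_is_all_normal(self):
        seg = segment_regions(np.zeros((20, 20)), 0.05, 0.5)
        assert (seg.labels == N_LABEL).all()

    def test_radial_density_gives_concentric_rings(self):
        r = raster(101)
        xg, yg = r.centers()
        rad = np.hypot(xg[:, None] - 1.0, yg[None, :] - 1.0)
        dens = np.clip(1.0 - rad, 0.0, 1.0)
        seg = segment_regions(dens, 0.2, 0.7, r)
        lab_center = seg.labels[50, 50]
        assert lab_center == CT_LABEL
        assert seg.labels[50, 85] == IF_LABEL    # rad ~ 0.7
        assert seg.labels[0, 0] == N_LABEL
        # labels partition the raster
        assert set(np.unique(seg.labels)) <= {N_LABEL, IF_LABEL, CT_LABEL}

    def test_equal_cutoffs_zero_measure_if(self):
        r = raster(41)
        xg, yg = r.centers()
        rad = np.hypot(xg[:, None] - 0.4, yg[None, :] - 0.4)
        dens = np.clip(1.0 - rad, 0.0, 1.0)
        seg = segment_regions(dens, 0.5, 0.5, r)
        assert not (seg.labels == IF_LABEL).any()

    def test_width_measurement_on_linear_ramp(self):
        r = raster(201)
        xg, yg = r.centers()
        rad = np.hypot(xg[:, None] - 2.0, yg[None, :] - 2.0)
        dens = np.clip(1.0 - 0.5 * rad, 0.0, 1.0)   # rho drops 0.5 per mm
        width, widths = mean_if_width(dens, r, 0.1, 0.6, center=(2.0, 2.0))
        assert width == pytest.approx(1.0, rel=0.03)
        assert np.nanstd(widths) < 0.05


class TestSyntheticTumorRecovery:
    def test_zero_width_is_hard_disc(self):
        df, truth = synthetic_radial_tumor(radius_mm=0.8, front_width_mm=0.0,
                                           n_tcells=0, seed=1)
        cancer = df[df["kind"] == "PC"]
        rr = np.hypot(cancer["ix"] - (truth["extent_mm"] / 0.02 - 1) / 2,
                      cancer["iy"] - (truth["extent_mm"] / 0.02 - 1) / 2) * 0.02
        assert rr.max() <= 0.8 + 0.03

    def test_determinism(self):
        a, _ = synthetic_radial_tumor(seed=5)
        b, _ = synthetic_radial_tumor(seed=5)
        assert a.equals(b)
        c, _ = synthetic_radial_tumor(seed=6)
        assert not a.equals(c)

    def test_front_recovered_within_ten_percent(self):
        """segment_regions on the synthetic logistic tumor: the mid-level
        contour radius matches the ground-truth front radius within 10%."""
        df, truth = synthetic_radial_tumor(radius_mm=1.0, front_width_mm=0.15,
                                           n_tcells=0, seed=3)
        cancer = df[df["kind"] == "PC"]
        pts = cancer[["ix", "iy"]].to_numpy(float) * truth["pixel_mm"]
        r = RasterSpec.cover(pts, pixel_mm=0.02, pad_mm=0.2)
        dens = kde2d(pts, 0.08, r)
        seg = segment_regions(dens, 0.1, 0.5, r)
        area_ct = (seg.labels == CT_LABEL).sum() * r.pixel_mm ** 2
        r_mid = math.sqrt(area_ct / math.pi)
        # rho=0.5 sits close to the logistic mid-radius
        assert r_mid == pytest.approx(1.0, rel=0.10)


class TestProfiles:
    def _setup(self, tcell_ring=1.0, n_tcells=500):
        df, truth = synthetic_radial_tumor(radius_mm=1.2, front_width_mm=0.15,
                                           n_tcells=n_tcells, seed=11,
                                           tcell_ring_mm=tcell_ring)
        px = truth["pixel_mm"]
        cancer = df[df["kind"] == "PC"][["ix", "iy"]].to_numpy(float) * px
        tcells = df[df["kind"] == "Teff"][["ix", "iy"]].to_numpy(float) * px
        r = RasterSpec.cover(cancer, pixel_mm=px, pad_mm=0.3)
        dens = kde2d(cancer, 0.08, r)
        seg = segment_regions(dens, 0.05, 0.6, r, sigma=0.08)
        return cancer, tcells, dens, seg

    def test_ring_of_tcells_peaks_at_front(self):
        cancer, tcells, dens, seg = self._setup(tcell_ring=1.2)
        prof = density_distance_profile(tcells, dens, seg, lam=1.0, n_boot=100)
        peak_r = prof.abscissa[np.argmax(prof.mean)]
        assert peak_r == pytest.approx(1.2, abs=0.25)
        assert not prof.degenerate
        assert np.all(prof.ci_lo <= prof.mean + 1e-12)
        assert np.all(prof.mean <= prof.ci_hi + 1e-12)

    def test_lambda_scaling_is_linear(self):
        cancer, tcells, dens, seg = self._setup()
        p1 = density_distance_profile(tcells, dens, seg, lam=1.0, n_boot=10)
        p6 = density_distance_profile(tcells, dens, seg, lam=6.0, n_boot=10)
        assert np.allclose(p6.mean, 6.0 * p1.mean)

    def test_no_tcells_degenerate_profile(self):
        cancer, _, dens, seg = self._setup(n_tcells=0)
        prof = density_distance_profile(np.empty((0, 2)), dens, seg, n_boot=10)
        assert prof.degenerate
        assert not prof.mean.any()

    def test_along_if_symmetric_ring_is_flat(self):
        cancer, tcells, dens, seg = self._setup(tcell_ring=1.2)
        prof = profile_along_if(tcells, seg, n_azimuth=8, lam=1.0, n_boot=50)
        vals = prof.mean[np.isfinite(prof.mean)]
        assert len(vals) == 8
        assert vals.std() / vals.mean() < 0.5   # no sector stands out

    def test_along_if_single_value_equals_band_mean(self):
        cancer, tcells, dens, seg = self._setup()
        prof = profile_along_if(tcells, seg, n_azimuth=1, lam=1.0, n_boot=10)
        assert len(prof.mean) == 1 and np.isfinite(prof.mean[0])

    def test_hotspot_at_known_azimuth(self):
        cancer, _, dens, seg = self._setup()
        cx, cy = density_centroid(dens, seg.raster)
        theta0 = 0.8
        band_r = 1.3
        hot = np.array([[cx + band_r * math.cos(theta0),
                         cy + band_r * math.sin(theta0)]]).repeat(120, axis=0)
        hot += np.random.default_rng(2).normal(0, 0.05, hot.shape)
        prof = profile_along_if(hot, seg, n_azimuth=12, lam=1.0, n_boot=20)
        j = np.nanargmax(prof.mean)
        assert prof.abscissa[j] == pytest.approx(theta0, abs=2 * math.pi / 12)
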