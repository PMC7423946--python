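"""Morphometry: profile extraction, spline fit, NBB/NBS/NBC geometry."""

import math

import numpy as np
import pytest

from osteoquant import morphometry as mm
from osteoquant.imaging_io import BinaryMask, FrameGeometry
from osteoquant.shell_model import ShellModel

from conftest import curve_mask_from_surface


class TestExtractDepthProfile:
    def test_single_line_already_thin(self):
        mask = np.zeros((20, 15), dtype=bool)
        mask[7, 2:12] = True
        prof = mm.extract_depth_profile(mask, (0.5, 0.5))
        np.testing.assert_allclose(prof.depth_mm[2:12], 7 * 0.5)
        assert np.isnan(prof.depth_mm[0])

    def test_lowest_depth_rule_for_stacked_lines(self):
        mask = np.zeros((20, 15), dtype=bool)
        mask[5, 2:12] = True
        mask[11, 2:12] = True
        prof = mm.extract_depth_profile(mask, (0.5, 0.5))
        np.testing.assert_allclose(prof.depth_mm[2:12], 5 * 0.5)

    def test_t_shaped_spur_pruned(self):
        """3-pixel stem hanging off a 15-pixel bar: the stem is pruned at
        prune length 5, the bar survives (hand-checked skeleton oracle)."""
        mask = np.zeros((20, 20), dtype=bool)
        mask[8, 2:17] = True   # bar
        mask[9:12, 9] = True   # stem below the bar center
        prof = mm.extract_depth_profile(mask, (1.0, 1.0), prune_len_px=5)
        np.testing.assert_allclose(prof.depth_mm[2:17], 8.0)
        # the stem would have left column 9 with a deeper junction pixel only;
        # the min-depth rule plus pruning keeps the bar depth
        assert prof.n_detected == 15

    def test_band_thins_to_centerline(self):
        mask = np.zeros((20, 16), dtype=bool)
        mask[6:9, 2:14] = True  # 3-pixel-thick band centered on row 7
        prof = mm.extract_depth_profile(mask, (1.0, 1.0))
        inner = prof.depth_mm[4:12]
        np.testing.assert_allclose(inner, 7.0)

    def test_bulk_envelope_mode(self):
        mask = np.zeros((20, 16), dtype=bool)
        mask[6:15, 2:14] = True  # solid block: envelope at row 6
        prof = mm.extract_depth_profile(mask, (1.0, 1.0), thin=False)
        np.testing.assert_allclose(prof.depth_mm[2:14], 6.0)

    def test_empty_slice_gives_empty_profile(self):
        prof = mm.extract_depth_profile(np.zeros((8, 8), dtype=bool), (1, 1))
        assert prof.n_detected == 0


class TestFitProfileSpline:
    def grid_profile(self, y):
        x = np.arange(len(y), dtype=float)
        return mm.DepthProfile(x, np.asarray(y, dtype=float))

    def test_collinear_points_reproduced_for_any_p(self):
        y = 2.0 + 0.3 * np.arange(12)
        for p in (0.0, 0.3, 0.5, 1.0):
            fit = mm.fit_profile_spline(
                self.grid_profile(y), mm.SplineConfig(smoothing_p=p)
            )
            np.testing.assert_allclose(fit.depth_mm, y, atol=1e-8)

    def test_p_one_interpolates_exactly(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 1.0, 15)
        fit = mm.fit_profile_spline(
            self.grid_profile(y), mm.SplineConfig(smoothing_p=1.0)
        )
        np.testing.assert_allclose(fit.depth_mm, y, atol=1e-9)

    def test_smoothing_trades_residual_for_curvature(self):
        """p=0.5 on noisy parabola samples: residuals above interpolation's
        (zero), curvature integral below interpolation's."""
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 40)
        y = 0.3 * (x - 5) ** 2 + rng.normal(0, 0.3, x.size)
        prof = mm.DepthProfile(x, y)
        smooth = mm.fit_profile_spline(prof, mm.SplineConfig(smoothing_p=0.5))
        interp = mm.fit_profile_spline(prof, mm.SplineConfig(smoothing_p=1.0))

        def curvature(yv):
            d2 = np.diff(yv, 2) / (x[1] - x[0]) ** 2
            return float((d2**2).sum())

        res_smooth = float(((smooth.depth_mm - y) ** 2).sum())
        res_interp = float(((interp.depth_mm - y) ** 2).sum())
        assert res_smooth > res_interp  # interpolation has ~zero residual
        assert curvature(smooth.depth_mm) < curvature(interp.depth_mm)

    def test_short_run_passes_through(self):
        y = np.full(10, np.nan)
        y[[1, 2, 3]] = [4.0, 6.0, 5.0]
        fit = mm.fit_profile_spline(self.grid_profile(y), mm.SplineConfig())
        np.testing.assert_allclose(fit.depth_mm[[1, 2, 3]], [4.0, 6.0, 5.0])

    def test_wide_gap_splits_runs(self):
        y = np.full(30, np.nan)
        y[0:8] = 5.0
        y[20:28] = 7.0
        fit = mm.fit_profile_spline(
            self.grid_profile(y), mm.SplineConfig(max_gap_columns=3)
        )
        assert len(fit.runs) == 2
        assert np.isnan(fit.depth_mm[10:18]).all()


def sector_mask(shell, R, t, phi, **kw):
    def radius(theta):
        rho = np.where(np.abs(theta) <= phi / 2, R + t, np.nan)
        return rho

    return curve_mask_from_surface(radius, shell, **kw)


class TestSectorGeometry:
    """Closed-form sector-ring values, verified against discrete oracles."""

    R, t, phi = 10.0, 2.0, math.pi / 2

    def shoelace_oracle(self):
        """High-resolution polygon of the true sector ring, shoelace area."""
        n = 20000
        th = np.linspace(-self.phi / 2, self.phi / 2, n)
        outer = np.stack(
            [(self.R + self.t) * np.cos(th), (self.R + self.t) * np.sin(th)], axis=1
        )
        inner = np.stack(
            [self.R * np.cos(th[::-1]), self.R * np.sin(th[::-1])], axis=1
        )
        poly = np.vstack([outer, inner])
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def test_closed_form_against_shoelace_oracle(self):
        analytic = 0.5 * self.phi * ((self.R + self.t) ** 2 - self.R**2)
        assert analytic == pytest.approx(self.shoelace_oracle(), rel=1e-6)

    def test_quantified_sector_matches_closed_form(
        self, single_slice_shell, frame_32mm
    ):
        mask = sector_mask(single_slice_shell, self.R, self.t, self.phi)
        out = mm.quantify_scan(mask, single_slice_shell, frame_32mm)
        assert len(out) == 1
        rec = out[0]
        assert rec.nbb_area_mm2 == pytest.approx(11 * math.pi, rel=0.02)
        assert rec.nbc_length_mm == pytest.approx(5 * math.pi, rel=0.02)
        assert rec.nbs_length_mm == pytest.approx(6 * math.pi + 4, rel=0.02)
        assert rec.nbc_norm_pct == pytest.approx(50.0, abs=1.0)
        assert rec.region == "M"

    def test_curve_on_shell_gives_zero_area(self, single_slice_shell, frame_32mm):
        mask = sector_mask(single_slice_shell, self.R, 0.0, math.pi * 0.8)
        out = mm.quantify_scan(mask, single_slice_shell, frame_32mm)
        if out:
            # rasterization leaves the band up to half a voxel proud of the
            # circle: residual area <= span * R * voxel/2 ~ 1.3 mm^2
            assert out[0].nbb_area_mm2 == pytest.approx(0.0, abs=1.5)

    def test_gap_arc_between_disjoint_deposits_added_to_nbs(
        self, single_slice_shell, frame_32mm
    ):
        R, t = self.R, 1.5
        spans = [(-1.2, -0.4), (0.3, 1.1)]
        psi = 0.3 - (-0.4)

        def radius(theta):
            rho = np.full_like(theta, np.nan)
            for lo, hi in spans:
                sel = (theta >= lo) & (theta <= hi)
                rho[sel] = R + t
            return rho

        mask = curve_mask_from_surface(radius, single_slice_shell)
        out = mm.quantify_scan(
            mask, single_slice_shell, frame_32mm,
            spline_cfg=mm.SplineConfig(max_gap_columns=2),
        )
        assert len(out) == 1
        expected_nbs = sum((hi - lo) * (R + t) + 2 * t for lo, hi in spans) + psi * R
        expected_nbc = sum((hi - lo) * R for lo, hi in spans)
        assert out[0].nbs_length_mm == pytest.approx(expected_nbs, rel=0.03)
        # steep interval ends (|theta| up to 69 deg) each lose up to one
        # column of arc: 4 ends x voxel / cos(69deg) * R / rho ~ 1.6 mm
        assert out[0].nbc_length_mm == pytest.approx(expected_nbc, abs=1.7)

    def test_nbb_zero_implies_nbs_nbc_zero(self, single_slice_shell, frame_32mm):
        mask = sector_mask(single_slice_shell, self.R, 0.0, 0.5)
        out = mm.quantify_scan(mask, single_slice_shell, frame_32mm)
        for rec in out:
            if rec.nbb_area_mm2 < 1e-6:
                assert rec.nbs_length_mm < 1e-3 or rec.nbc_length_mm < 1e-3

    def test_perimeter_partition_identity_single_deposit(
        self, single_slice_shell, frame_32mm
    ):
        """For one connected deposit, NBS + NBC equals the region perimeter
        (curve + radial drops + contact arc)."""
        mask = sector_mask(single_slice_shell, self.R, self.t, self.phi)
        rec = mm.quantify_scan(mask, single_slice_shell, frame_32mm)[0]
        perimeter = (
            self.phi * (self.R + self.t) + 2 * self.t + self.phi * self.R
        )
        assert rec.nbs_length_mm + rec.nbc_length_mm == pytest.approx(
            perimeter, rel=0.02
        )


class TestInvariances:
    def test_isotropic_scaling(self, frame_32mm):
        """Scaling lengths by s scales NBB by s^2, NBS/NBC by s, and leaves
        normalized values unchanged."""
        s = 2.0
        recs = {}
        for scale, vox, grid in ((1.0, 0.2, (160, 144, 1)), (s, 0.4, (160, 144, 1))):
            shell = ShellModel(
                (17.6 * scale, 14.4 * scale, -10.0 * scale),
                (0, 0, 1),
                10.0 * scale,
                20.0 * scale,
            )
            frame = FrameGeometry(28.8 * scale, 32.0 * scale)
            mask = sector_mask(
                shell, 10.0 * scale, 2.0 * scale, math.pi / 2,
                voxel_mm=vox, grid_shape=grid, slice_z_mm=0.0,
            )
            recs[scale] = mm.quantify_scan(mask, shell, frame)[0]
        a, b = recs[1.0], recs[s]
        assert b.nbb_area_mm2 == pytest.approx(s**2 * a.nbb_area_mm2, rel=0.02)
        assert b.nbs_length_mm == pytest.approx(s * a.nbs_length_mm, rel=0.02)
        assert b.nbc_length_mm == pytest.approx(s * a.nbc_length_mm, rel=0.02)
        assert b.nbb_norm_pct == pytest.approx(a.nbb_norm_pct, rel=0.02)
        assert b.nbs_norm == pytest.approx(a.nbs_norm, rel=0.02)
        assert b.nbc_norm_pct == pytest.approx(a.nbc_norm_pct, rel=0.02)

    def test_in_plane_rotation(self, single_slice_shell, frame_32mm):
        """Rotating the deposit sector about the shell axis (within the
        visible half) changes the markers by < 1%."""
        rot = math.radians(5.0)
        base = mm.quantify_scan(
            sector_mask(single_slice_shell, 10.0, 2.0, math.pi / 2),
            single_slice_shell,
            frame_32mm,
        )[0]

        def radius(theta):
            return np.where(np.abs(theta - rot) <= math.pi / 4, 12.0, np.nan)

        rotated = mm.quantify_scan(
            curve_mask_from_surface(radius, single_slice_shell),
            single_slice_shell,
            frame_32mm,
        )[0]
        assert rotated.nbb_area_mm2 == pytest.approx(base.nbb_area_mm2, rel=0.01)
        assert rotated.nbs_length_mm == pytest.approx(base.nbs_length_mm, rel=0.01)
        assert rotated.nbc_length_mm == pytest.approx(base.nbc_length_mm, rel=0.01)

    def test_nbc_bounded_by_circumference(self, single_slice_shell, frame_32mm):
        mask = sector_mask(single_slice_shell, 10.0, 1.0, math.pi - 0.05)
        rec = mm.quantify_scan(mask, single_slice_shell, frame_32mm)[0]
        assert rec.nbc_length_mm <= 2 * math.pi * 10.0
        assert rec.nbc_norm_pct <= 100.0 + 2.0


class TestCommonRangeAndDistance:
    def two_masks(self):
        a = np.zeros((16, 24, 10), dtype=bool)
        b = np.zeros((16, 24, 10), dtype=bool)
        a[8, 4:20, 2:8] = True
        b[8, 8:22, 4:9] = True
        vox = (0.5, 0.5, 0.5)
        return BinaryMask(a, vox), BinaryMask(b, vox)

    def test_identical_masks_unchanged(self):
        a, _ = self.two_masks()
        ra, rb = mm.common_range_restrict(a, a)
        np.testing.assert_array_equal(ra.values, a.values)
        np.testing.assert_array_equal(rb.values, a.values)

    def test_intersection_restricts_both(self):
        a, b = self.two_masks()
        ra, rb = mm.common_range_restrict(a, b)
        # common columns 8..19, common slices 4..7
        assert not ra.values[:, :8, :].any()
        assert not ra.values[:, :, :4].any()
        assert ra.values[8, 8:20, 4:8].all()
        assert rb.values[8, 8:20, 4:8].all()

    def test_disjoint_ranges_empty_both(self):
        a = np.zeros((8, 16, 6), dtype=bool)
        b = np.zeros((8, 16, 6), dtype=bool)
        a[4, 0:4, :] = True
        b[4, 10:14, :] = True
        ra, rb = mm.common_range_restrict(
            BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))
        )
        assert not ra.values.any() and not rb.values.any()

    def profile(self, depths, z=0.0):
        return mm.DepthProfile(
            np.arange(len(depths), dtype=float), np.asarray(depths, float),
            slice_z_mm=z,
        )

    def test_identical_surfaces_distance_zero(self):
        p = [self.profile(np.full(50, 5.0))]
        rep = mm.mean_absolute_distance(p, p)
        assert rep.mean_abs_distance_mm == 0.0

    def test_constant_offset_recovered(self):
        a = [self.profile(np.full(200, 5.0))]
        b = [self.profile(np.full(200, 5.5))]
        rep = mm.mean_absolute_distance(a, b)
        assert rep.mean_abs_distance_mm == pytest.approx(0.5, rel=1e-6)

    def test_sine_offset_mean_matches_integral(self):
        """B = A + 0.3 sin: nearest-point distance ~ vertical distance for a
        slowly varying offset; mean |0.3 sin| = 0.3 * 2/pi."""
        x = np.linspace(0, 400, 8000)
        a = [mm.DepthProfile(x, np.full(x.size, 10.0))]
        b = [mm.DepthProfile(x, 10.0 + 0.3 * np.sin(2 * np.pi * x / 100.0))]
        rep = mm.mean_absolute_distance(a, b)
        assert rep.mean_abs_distance_mm == pytest.approx(0.3 * 2 / math.pi, rel=0.02)

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mm.mean_absolute_distance(
                [self.profile(np.full(5, np.nan))], [self.profile(np.full(5, 1.0))]
            )
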