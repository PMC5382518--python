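"""Correlation displacement estimator: primitives and pipeline."""

import numpy as np
import pytest

import civstrain as cs
from civstrain import civcore as cc
from civstrain.exceptions import DataError, ParameterError


class TestCorrelationSurface:
    def test_autocorrelation_unit_peak_at_zero(self, small_grid, small_params):
        corr, origin = cc.correlation_surface(small_grid, small_grid, (48, 48),
                                              small_params)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        assert (origin[0] + ix, origin[1] + iy) == (0, 0)
        assert corr.max() == pytest.approx(1.0, abs=1e-9)
        assert corr.min() >= -1.0 and corr.max() <= 1.0

    def test_known_integer_shift(self, small_grid, small_params):
        shifted = np.roll(small_grid, (0, 5), axis=(0, 1))
        corr, origin = cc.correlation_surface(small_grid, shifted, (48, 48),
                                              small_params)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        assert (origin[0] + ix, origin[1] + iy) == (5, 0)

    def test_blank_window_degenerate(self, small_params):
        img = np.zeros((96, 96))
        img[:, :4] = 1.0
        with pytest.raises(cc.DegenerateWindowError):
            cc.correlation_surface(img, img, (60, 60), small_params)

    @pytest.mark.parametrize("shift", [(3, 0), (0, -2), (-2, 2)])
    def test_matches_bruteforce_oracle(self, shift, ncc_bruteforce):
        rng = np.random.default_rng(11)
        img1 = rng.random((64, 64))
        du, dv = shift
        img2 = np.roll(img1, (dv, du), axis=(0, 1))
        params = cs.CivParams(correlation_box=9, search_box=15)
        corr, origin = cc.correlation_surface(img1, img2, (32, 32), params)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        oracle, _ = ncc_bruteforce(img1, img2, (32, 32), 9, 15)
        assert (origin[0] + ix, origin[1] + iy) == oracle == shift


class TestSubpixelPeak:
    def test_symmetric_peak_on_node(self):
        x, y = np.meshgrid(np.arange(9), np.arange(9))
        corr = np.exp(-((x - 4.0) ** 2 + (y - 4.0) ** 2) / 4.0)
        px, py, peak = cc.subpixel_peak(corr)
        assert (px, py) == (4.0, 4.0)
        assert peak == pytest.approx(1.0)

    @pytest.mark.parametrize("frac", [0.3, -0.3, 0.12])
    def test_gaussian_offset_recovery(self, frac):
        x, y = np.meshgrid(np.arange(11), np.arange(9))
        corr = np.exp(-((x - (5 + frac)) ** 2 + (y - 4.0) ** 2) / 3.0)
        px, py, _ = cc.subpixel_peak(corr)
        assert px == pytest.approx(5 + frac, abs=0.02)
        assert py == pytest.approx(4.0, abs=0.02)

    def test_border_peak_raises(self):
        corr = np.zeros((7, 7))
        corr[0, 3] = 1.0
        with pytest.raises(cc.BorderPeakError):
            cc.subpixel_peak(corr)

    def test_refinement_within_half_pixel(self):
        rng = np.random.default_rng(3)
        corr = rng.random((9, 9)) * 0.2
        corr[4, 5] = 1.0
        px, py, _ = cc.subpixel_peak(corr)
        assert abs(px - 5) <= 0.5 and abs(py - 4) <= 0.5


class TestCivPass:
    def test_identity_pair_zero_field(self, small_grid, small_params):
        res = cs.CIVModel(small_grid, small_grid, small_params).fit()
        d = np.hypot(res.field.u, res.field.v)
        assert d.max() < 0.05

    def test_uniform_subpixel_shift(self, small_grid, small_params):
        shape = small_grid.shape
        moved = cs.warp_image(small_grid, (np.full(shape, 5.3),
                                           np.full(shape, -2.7)))
        res = cs.CIVModel(small_grid, moved, small_params).fit()
        m = res.field.valid_mask()
        assert np.mean(res.field.u[m]) == pytest.approx(5.3, abs=0.1)
        assert np.mean(res.field.v[m]) == pytest.approx(-2.7, abs=0.1)

    def test_integer_shift_exact(self, small_grid, small_params):
        moved = np.roll(small_grid, (0, 5), axis=(0, 1))
        res = cs.CIVModel(small_grid, moved, small_params).fit()
        m = res.field.valid_mask()
        assert np.mean(res.field.u[m]) == pytest.approx(5.0, abs=0.05)
        assert np.mean(res.field.v[m]) == pytest.approx(0.0, abs=0.05)

    def test_swap_antisymmetry(self, small_pair, small_params):
        img1, img2 = small_pair
        f12 = cs.CIVModel(img1, img2, small_params).fit().field
        f21 = cs.CIVModel(img2, img1, small_params).fit().field
        resid = np.hypot(f12.u + f21.u, f12.v + f21.v)
        both_valid = f12.valid_mask() & f21.valid_mask()
        interior = np.zeros_like(both_valid)
        interior[1:-1, 1:-1] = True
        assert resid[both_valid & interior].max() < 0.1

    def test_invalid_params(self, small_grid):
        with pytest.raises(ParameterError):
            cs.CIVModel(small_grid, small_grid,
                        cs.CivParams(correlation_box=31, search_box=15))

    def test_unequal_sizes(self, small_grid):
        with pytest.raises(DataError):
            cs.CIVModel(small_grid, small_grid[:-8])

    def test_low_flagged_fraction_on_clean_experiment(self, small_fit):
        # on a clean synthetic pair essentially only frame-border boxes
        # (whose content can leave the field of view) need replacement
        f = small_fit.field
        inner = f.flags[1:-1, 1:-1]
        assert np.count_nonzero(inner != cc.FLAG_VALID) / inner.size < 0.05


class TestOutlierRejection:
    def _uniform_field(self):
        x = y = np.arange(5, dtype=float) * 8 + 8
        u = np.full((5, 5), 1.5)
        v = np.full((5, 5), -0.5)
        corr = np.full((5, 5), 0.9)
        flags = np.zeros((5, 5), dtype=np.int8)
        return cc.VectorField(x, y, u, v, corr, flags)

    def test_spike_replaced_by_neighbour_median(self):
        field = self._uniform_field()
        field.u[2, 2] = 11.5  # 10 px spike
        out = cc.reject_outliers(field, cs.CivParams(15, 31))
        assert out.u[2, 2] == pytest.approx(1.5)
        assert out.flags[2, 2] == cc.FLAG_FILLED

    def test_constant_field_unchanged(self):
        field = self._uniform_field()
        out = cc.reject_outliers(field, cs.CivParams(15, 31))
        assert np.array_equal(out.u, field.u)
        assert np.array_equal(out.flags, field.flags)

    def test_low_correlation_replaced(self):
        field = self._uniform_field()
        field.corr[1, 1] = 0.1
        out = cc.reject_outliers(field, cs.CivParams(15, 31))
        assert out.flags[1, 1] == cc.FLAG_FILLED

    def test_rejected_cluster_filled_by_cascade(self):
        field = self._uniform_field()
        field.flags[:2, :2] = cc.FLAG_REJECTED
        field.u[:2, :2] = 0.0
        out = cc.reject_outliers(field, cs.CivParams(15, 31))
        assert np.all(out.flags != cc.FLAG_REJECTED)
        assert np.allclose(out.u, 1.5)


class TestSmoothing:
    def _linear_field(self):
        x = y = np.arange(7, dtype=float) * 8 + 8
        xx, yy = np.meshgrid(x, y)
        u = 0.02 * xx - 0.01 * yy + 0.3
        v = 0.015 * yy
        return cc.VectorField(x, y, u, v, np.ones_like(u),
                              np.zeros(u.shape, dtype=np.int8))

    def test_linear_field_invariant(self):
        field = self._linear_field()
        out = cc.smooth_field(field, cs.CivParams(15, 31))
        assert np.max(np.abs(out.u - field.u)) < 1e-6
        assert np.max(np.abs(out.v - field.v)) < 1e-6

    def test_noise_variance_reduced(self):
        field = self._linear_field()
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.2, field.u.shape)
        field.u = field.u + noise
        out = cc.smooth_field(field, cs.CivParams(15, 31))
        linear = self._linear_field().u
        assert np.var(out.u - linear) < np.var(noise)

    def test_smoothing_reduces_recovery_error(self, small_pair, small_params,
                                              small_flow):
        img1, img2 = small_pair
        field = cc.reject_outliers(
            cc.civ_pass(img1, img2, small_params), small_params)
        smoothed = cc.smooth_field(field, small_params)
        gx, gy = np.meshgrid(field.x, field.y)
        tu, tv = cs.analytic_displacement(gx, gy, small_flow)
        err_raw = np.mean(np.hypot(field.u - tu, field.v - tv))
        err_smooth = np.mean(np.hypot(smoothed.u - tu, smoothed.v - tv))
        assert err_smooth < err_raw


class TestInterpolation:
    def test_exact_at_measurement_points(self, small_fit):
        f = small_fit.field
        pts = np.array([[f.x[2], f.y[3]], [f.x[0], f.y[0]]])
        u, v = cc.interpolate_field(f, pts)
        assert u[0] == pytest.approx(f.u[3, 2], abs=1e-9)
        assert v[1] == pytest.approx(f.v[0, 0], abs=1e-9)

    def test_linear_reproduction(self):
        x = y = np.arange(6, dtype=float) * 10
        xx, yy = np.meshgrid(x, y)
        field = cc.VectorField(x, y, 0.1 * xx + 0.05 * yy, -0.02 * xx,
                               np.ones_like(xx), np.zeros(xx.shape, np.int8))
        qx = np.array([[13.7, 22.1], [40.0, 49.9]])
        u, v = cc.interpolate_field(field, qx)
        assert np.allclose(u, 0.1 * qx[:, 0] + 0.05 * qx[:, 1], atol=1e-6)
        assert np.allclose(v, -0.02 * qx[:, 0], atol=1e-6)

    def test_too_few_vectors(self):
        x = np.array([0.0])
        field = cc.VectorField(x, x, [[1.0]], [[1.0]], [[1.0]],
                               np.zeros((1, 1), np.int8))
        with pytest.raises(DataError):
            cc.interpolate_field(field, (8, 8))

    def test_dense_rms_against_analytic(self, small_fit, small_flow):
        u, v = small_fit.dense()
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        tu, tv = cs.analytic_displacement(xx, yy, small_flow)
        inner = (slice(12, -12), slice(12, -12))
        rms = np.sqrt(np.mean((u[inner] - tu[inner]) ** 2
                              + (v[inner] - tv[inner]) ** 2))
        assert rms < 0.5


class TestVectorFieldRoundtrip:
    def test_dataframe_roundtrip(self, small_fit):
        f = small_fit.field
        back = cc.VectorField.from_dataframe(f.to_dataframe())
        assert np.allclose(back.u, f.u)
        assert np.allclose(back.v, f.v)
        assert np.array_equal(back.flags, f.flags)


def test_results_summary_mentions_key_settings(small_fit):
    text = small_fit.summary()
    assert "correlation box" in text
    assert "15" in text and "31" in text
    assert "valid vectors" in text
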