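"""Affine removal, polynomial distortion fit, displacement statistics."""
import numpy as np
import pytest

import scanwarp as sw
from scanwarp._poly import Normalization, n_terms
from scanwarp.errors import (
    BoundsError,
    DegenerateGeometryError,
    InsufficientPointsError,
)
from scanwarp.synthetic import identity_warp


def grid_points(w, h, step=40.0):
    xs = np.arange(0.0, w, step)
    ys = np.arange(0.0, h, step)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


class TestFitAffine:
    def test_identity(self):
        pts = grid_points(200, 160)
        amap, aligned = sw.fit_affine(pts, pts)
        np.testing.assert_allclose(amap.linear, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(amap.translation, 0.0, atol=1e-10)
        assert amap.fit_residual_rms < 1e-10
        np.testing.assert_allclose(aligned, pts, atol=1e-9)

    def test_recovers_rotation_translation(self):
        pts = grid_points(200, 160)
        theta = np.radians(12.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        t = np.array([7.5, -3.25])
        measured = pts @ rot.T + t
        amap, aligned = sw.fit_affine(pts, measured)
        np.testing.assert_allclose(amap.linear, rot, atol=1e-9)
        np.testing.assert_allclose(amap.translation, t, atol=1e-9)
        np.testing.assert_allclose(aligned, measured, atol=1e-9)

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0.0], [10.0, 5.0], [20.0, 10.0], [30.0, 15.0]])
        with pytest.raises(DegenerateGeometryError):
            sw.fit_affine(pts, pts)

    def test_least_squares_optimality_under_perturbation(self):
        rng = np.random.default_rng(0)
        pts = grid_points(200, 160)
        measured = pts + rng.normal(0, 1.0, pts.shape)
        amap, aligned = sw.fit_affine(pts, measured)
        base = np.mean(np.sum((measured - aligned) ** 2, axis=1))
        for _ in range(20):
            d_lin = rng.normal(0, 1e-3, (2, 2))
            d_t = rng.normal(0, 1e-2, 2)
            pert = pts @ (amap.linear + d_lin).T + amap.translation + d_t
            assert np.mean(np.sum((measured - pert) ** 2, axis=1)) >= base

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            sw.fit_affine(np.zeros((2, 2)), np.zeros((2, 2)))


class TestFitPolynomial:
    def test_zero_residual_gives_identity(self):
        pts = grid_points(400, 300)
        field = sw.fit_polynomial(pts, pts, degree=3, field_dims=(400, 300))
        assert field.fit_rms < 1e-9
        probe = grid_points(400, 300, 17.0)
        np.testing.assert_allclose(field(probe), probe, atol=1e-9)

    def test_recovers_injected_cubic_warp(self):
        # known cubic displacement; fit must reproduce the displacement
        # field to well under 0.01 px everywhere
        w, h = 800, 600
        rng = np.random.default_rng(1)
        nt = n_terms(3)
        warp = identity_warp((w, h), degree=3)
        warp = sw.WarpSpec(
            affine=warp.affine,
            poly_coeff_x=rng.normal(0, 2.0, nt),
            poly_coeff_y=rng.normal(0, 2.0, nt),
            degree=3, norm=warp.norm,
        )
        pts = grid_points(w, h, 40.0)
        measured = sw.apply_warp(pts, warp)
        field = sw.fit_polynomial(pts, measured, degree=3, field_dims=(w, h))
        probe = grid_points(w, h, 13.0)
        np.testing.assert_allclose(
            field(probe), sw.apply_warp(probe, warp), atol=0.01
        )
        assert field.fit_rms < 1e-8

    def test_degree1_after_affine_removal_is_null(self):
        rng = np.random.default_rng(2)
        pts = grid_points(400, 300)
        measured = pts @ np.array([[1.02, 0.01], [-0.02, 0.98]]).T + [3.0, -4.0]
        amap, aligned = sw.fit_affine(pts, measured)
        field = sw.fit_polynomial(aligned, measured, degree=1, field_dims=(400, 300))
        probe = grid_points(400, 300, 23.0)
        assert np.max(np.abs(field(probe) - probe)) < 1e-6

    def test_underdetermined_rejected_with_count(self):
        pts = grid_points(100, 100, 60.0)  # 4 points < 10 coefficients
        with pytest.raises(InsufficientPointsError) as exc:
            sw.fit_polynomial(pts, pts, degree=3, field_dims=(100, 100))
        assert exc.value.n_required == n_terms(3)

    def test_overparameterized_fit_warns(self):
        pts = grid_points(200, 200, 50.0)  # 16 points
        with pytest.warns(UserWarning, match="chase noise"):
            sw.fit_polynomial(pts, pts, degree=3, field_dims=(200, 200))


class TestDisplacementStats:
    def test_identity_field_zero_stats(self):
        pts = grid_points(400, 300)
        field = sw.fit_distortion(pts, pts, degree=3, field_dims=(400, 300))
        stats, mag = sw.displacement_stats(field, sample_step=16)
        assert stats.rms_px < 1e-9
        assert stats.max_px < 1e-9
        assert mag.shape == (round(300 / 16), round(400 / 16))

    @pytest.mark.parametrize("rms,width,expected", [
        (9.68, 24000.0, 0.04033333333333333),
        (0.19, 4096.0, 0.004638671875),
    ])
    def test_rms_percent_is_rms_over_width(self, rms, width, expected):
        assert sw.rms_percent(rms, width) == pytest.approx(expected, rel=1e-12)

    def test_affine_invariance_of_rms(self):
        # composing an extra affine onto the measured points changes the
        # fitted affine but not the reported displacement statistics
        w, h = 900, 700
        lat = sw.hex_lattice(12, 12, 55.0, origin=(80, 80))
        pts, _ = sw.generate_lattice_points(lat)
        warp = sw.synthetic.random_warp(5, lat, (w, h), target_rms=6.0)
        measured = sw.apply_warp(pts, warp)

        def fit_stats(meas):
            amap, aligned = sw.fit_affine(pts, meas)
            c = pts.mean(axis=0)
            field = sw.fit_polynomial(
                aligned, meas, degree=3, field_dims=(w, h),
                frame_center=(c[0], c[1]), affine=amap,
            )
            return sw.displacement_stats(field, sample_step=32)[0]

        base = fit_stats(measured)
        rng = np.random.default_rng(6)
        for _ in range(5):
            lin = np.eye(2) + rng.normal(0, 0.05, (2, 2))
            t = rng.normal(0, 50.0, 2)
            stats = fit_stats(measured @ lin.T + t)
            assert stats.rms_px == pytest.approx(base.rms_px, abs=1e-6)
            assert stats.max_px == pytest.approx(base.max_px, abs=1e-6)

    def test_stride_insensitivity_on_smooth_field(self):
        # quadrature error scales like (stride / field size)^2, so stride 16
        # on a realistically sized field changes the rms by far less than 0.1%
        w, h = 1600, 1280
        lat = sw.hex_lattice(12, 12, 110.0, origin=(120, 120))
        pts, _ = sw.generate_lattice_points(lat)
        warp = sw.synthetic.random_warp(7, lat, (w, h), target_rms=4.0)
        field = sw.fit_distortion(pts, sw.apply_warp(pts, warp),
                                  degree=3, field_dims=(w, h))
        rms1 = sw.displacement_stats(field, sample_step=1)[0].rms_px
        rms16 = sw.displacement_stats(field, sample_step=16)[0].rms_px
        assert abs(rms16 - rms1) / rms1 < 1e-3

    @pytest.mark.parametrize("k3", [2.0, 8.0, -5.0])
    def test_crop_reduces_rms_for_radial_distortion(self, k3):
        # pincushion/barrel: displacement ~ k3 * r^3 growing toward the
        # edges, so a centered crop evaluated against its own affine must
        # report less distortion than the full field
        w, h = 1000, 1000
        pts = grid_points(w, h, 50.0)
        norm = Normalization.for_field((w, h))
        u = norm(pts)
        r2 = (u**2).sum(axis=1, keepdims=True)
        measured = pts + k3 * r2 * u
        field = sw.fit_distortion(pts, measured, degree=3, field_dims=(w, h))
        full = sw.displacement_stats(field, sample_step=20)[0]
        crop = sw.displacement_stats(
            field, sample_step=20, crop=(300, 300, 400, 400)
        )[0]
        assert crop.rms_px <= full.rms_px
        assert crop.rms_percent == pytest.approx(
            crop.rms_px / 400 * 100, rel=1e-12
        )

    def test_crop_outside_field_rejected(self):
        pts = grid_points(400, 300)
        field = sw.fit_distortion(pts, pts, degree=1, field_dims=(400, 300))
        with pytest.raises(BoundsError):
            sw.displacement_stats(field, crop=(300, 100, 200, 100))

    def test_refit_affine_free_linear_part(self):
        # after the pipeline's affine pre-removal, refitting an affine to
        # (p, T(p)) at the fit points must give a near-identity linear part
        # (least-squares orthogonality of the pre-removed affine)
        w, h = 800, 600
        lat = sw.hex_lattice(10, 10, 60.0, origin=(70, 70))
        pts, _ = sw.generate_lattice_points(lat)
        measured = sw.apply_warp(pts, sw.synthetic.random_warp(9, lat, (w, h), 4.0))
        amap, aligned = sw.fit_affine(pts, measured)
        field = sw.fit_polynomial(aligned, measured, degree=3, field_dims=(w, h))
        refit, _ = sw.fit_affine(aligned, field(aligned))
        np.testing.assert_allclose(refit.linear, np.eye(2), atol=1e-6)
        np.testing.assert_allclose(refit.translation, 0.0, atol=1e-6)
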