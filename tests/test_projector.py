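"""Perspective DRR rendering and supervision losses."""

import math

import numpy as np
import pytest

from orthoreg import (DRRImage, Pose6DoF, ProjectionGeometry, Volume,
                      contrast_adjust, lat_view_transform,
                      perspective_projection_loss, reconstruction_loss,
                      render_biplanar, render_drr, total_generator_loss)
from orthoreg.geometry import compose, pose_to_matrix
from orthoreg.projector import save_drr, load_drr


def cube_volume(side_mm=64.0, spacing=2.0, value=1.0):
    """Homogeneous cube of the given side, centered at the world origin."""
    n = int(side_mm / spacing) + 1
    vox = np.full((n, n, n), value)
    half = (n - 1) / 2 * spacing
    return Volume(vox, (spacing,) * 3, (-half, -half, -half))


def gaussian_ball(n=33, spacing=2.0, sigma_mm=12.0, center=(0, 0, 0)):
    half = (n - 1) / 2 * spacing
    ax = np.arange(n) * spacing - half
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2)
    return Volume(np.exp(-r2 / (2 * sigma_mm ** 2)), (spacing,) * 3,
                  (-half, -half, -half))


class TestRenderDRR:
    def test_zero_volume_zero_image(self):
        vol = Volume(np.zeros((9, 9, 9)), (2, 2, 2), (-8, -8, -8))
        img = render_drr(vol, Pose6DoF(), ProjectionGeometry(
            detector_shape=(5, 5)))
        np.testing.assert_array_equal(img.pixels, 0.0)

    def test_cube_chord_matches_analytic(self):
        # line integral through a unit-intensity cube = source-to-pixel
        # chord length through the cube
        step = 0.5
        vol = cube_volume(side_mm=64.0)
        geom = ProjectionGeometry(detector_shape=(5, 5), pixel_spacing=(8, 8),
                                  step=step)
        img = render_drr(vol, Pose6DoF(), geom)
        sid, sdd = geom.sid, geom.sdd
        for (i, j) in [(2, 2), (2, 3), (3, 4)]:
            u = (i - 2) * 8.0
            v = (j - 2) * 8.0
            # entry/exit on the x = +/-32 planes; the ray stays inside the
            # lateral faces for these small detector offsets
            chord = 64.0 * math.sqrt(sdd ** 2 + u ** 2 + v ** 2) / sdd
            assert img.pixels[i, j] == pytest.approx(chord, abs=2 * step)

    def test_halving_step_refines_quadrature(self):
        vol = cube_volume(side_mm=64.0)
        imgs = {}
        for step in (2.0, 1.0):
            geom = ProjectionGeometry(detector_shape=(3, 3),
                                      pixel_spacing=(8, 8), step=step)
            imgs[step] = render_drr(vol, Pose6DoF(), geom).pixels[1, 1]
        assert abs(imgs[1.0] - imgs[2.0]) < 1.0

    def test_linearity_in_intensity(self):
        vol = gaussian_ball()
        geom = ProjectionGeometry(detector_shape=(7, 7), pixel_spacing=(6, 6))
        base = render_drr(vol, Pose6DoF(), geom).pixels
        doubled = render_drr(Volume(2 * vol.voxels, vol.spacing, vol.origin),
                             Pose6DoF(), geom).pixels
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-9, atol=1e-12)

    def test_in_plane_shift_equivariance_orthographic_limit(self):
        # at a very large source distance, moving the volume by one detector
        # pixel shifts the image by one pixel
        vol = gaussian_ball(sigma_mm=8.0)
        geom = ProjectionGeometry(sid=1e6, sdd=1e6 + 500,
                                  detector_shape=(15, 15),
                                  pixel_spacing=(4, 4))
        base = render_drr(vol, Pose6DoF(), geom).pixels
        shifted = render_drr(vol, Pose6DoF(ty=4.0), geom).pixels
        scale = base.max()
        np.testing.assert_allclose(shifted[1:, :] / scale,
                                   base[:-1, :] / scale, atol=0.02)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(sid=1500, sdd=1000)
        with pytest.raises(ValueError):
            ProjectionGeometry(step=-1.0)


class TestBiplanar:
    def test_symmetric_phantom_ap_equals_lat(self):
        vol = gaussian_ball()
        geom_ap = ProjectionGeometry(detector_shape=(9, 9), pixel_spacing=(6, 6))
        geom_lat = ProjectionGeometry(detector_shape=(9, 9), pixel_spacing=(6, 6),
                                      view=lat_view_transform(90.0),
                                      view_tag="LAT")
        ap, lat = render_biplanar(vol, Pose6DoF(), geom_ap, geom_lat)
        np.testing.assert_allclose(ap.pixels, lat.pixels, atol=1e-6)

    def test_off_center_blob_follows_pinhole_magnification(self):
        # blob at depth x0, offset y0: projected offset = y0 * sdd / (sid + x0)
        x0, y0 = 10.0, 12.0
        vol = gaussian_ball(n=41, spacing=2.0, sigma_mm=4.0, center=(x0, y0, 0))
        geom = ProjectionGeometry(detector_shape=(41, 41), pixel_spacing=(2, 2))
        img = render_drr(vol, Pose6DoF(), geom).pixels
        i_peak = np.unravel_index(np.argmax(img), img.shape)[0]
        u_peak = (i_peak - 20) * 2.0
        u_pred = y0 * geom.sdd / (geom.sid + x0)
        assert abs(u_peak - u_pred) <= 2.0  # within one pixel

    def test_two_quarter_turns_equal_half_turn_view(self):
        q = lat_view_transform(90.0)
        half = pose_to_matrix(Pose6DoF(gamma=math.pi))
        np.testing.assert_allclose(compose(q, q).matrix, half.matrix,
                                   atol=1e-12)
        vol = gaussian_ball(center=(6, 3, -4))
        geom_a = ProjectionGeometry(detector_shape=(9, 9), pixel_spacing=(6, 6),
                                    view=compose(q, q))
        geom_b = ProjectionGeometry(detector_shape=(9, 9), pixel_spacing=(6, 6),
                                    view=half)
        np.testing.assert_allclose(render_drr(vol, Pose6DoF(), geom_a).pixels,
                                   render_drr(vol, Pose6DoF(), geom_b).pixels,
                                   atol=1e-12)


class TestLosses:
    def test_reconstruction_loss_identical_is_zero(self, bone_volume):
        assert reconstruction_loss(bone_volume, bone_volume) == 0.0

    def test_reconstruction_loss_constant_offset(self, bone_volume):
        shifted = Volume(bone_volume.voxels + 3.0, bone_volume.spacing,
                         bone_volume.origin)
        assert reconstruction_loss(shifted, bone_volume) == pytest.approx(9.0)

    def test_reconstruction_loss_matches_nested_loops(self, rng):
        a = Volume(rng.normal(size=(4, 4, 4)), (1, 1, 1))
        b = Volume(rng.normal(size=(4, 4, 4)), (1, 1, 1))
        acc = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    acc += (a.voxels[i, j, k] - b.voxels[i, j, k]) ** 2
        assert reconstruction_loss(a, b) == pytest.approx(acc / 64, abs=1e-12)

    def test_projection_loss_self_render_is_zero(self):
        vol = gaussian_ball()
        ga = ProjectionGeometry(detector_shape=(5, 5), pixel_spacing=(8, 8))
        gl = ProjectionGeometry(detector_shape=(5, 5), pixel_spacing=(8, 8),
                                view=lat_view_transform(90.0))
        ap = render_drr(vol, Pose6DoF(), ga)
        lat = render_drr(vol, Pose6DoF(), gl)
        assert perspective_projection_loss(vol, ap, lat, ga, gl) == 0.0

    def test_projection_loss_zero_volume_unit_targets(self):
        vol = Volume(np.zeros((9, 9, 9)), (2, 2, 2), (-8, -8, -8))
        ga = ProjectionGeometry(detector_shape=(3, 3), pixel_spacing=(4, 4))
        gl = ProjectionGeometry(detector_shape=(3, 3), pixel_spacing=(4, 4),
                                view=lat_view_transform(90.0))
        ones = DRRImage(np.ones((3, 3)), (4, 4))
        assert perspective_projection_loss(vol, ones, ones, ga, gl) == \
            pytest.approx(1.0)

    def test_projection_loss_two_pixel_arithmetic(self):
        vol = Volume(np.zeros((9, 9, 9)), (2, 2, 2), (-8, -8, -8))
        ga = ProjectionGeometry(detector_shape=(1, 2), pixel_spacing=(4, 4))
        gl = ProjectionGeometry(detector_shape=(1, 2), pixel_spacing=(4, 4),
                                view=lat_view_transform(90.0))
        ap = DRRImage(np.array([[3.0, 1.0]]), (4, 4))
        lat = DRRImage(np.array([[2.0, 4.0]]), (4, 4))
        expected = 0.5 * ((9 + 1) / 2 + (4 + 16) / 2)
        assert perspective_projection_loss(vol, ap, lat, ga, gl) == \
            pytest.approx(expected)

    def test_projection_loss_shape_mismatch_rejected(self):
        vol = Volume(np.zeros((9, 9, 9)), (2, 2, 2), (-8, -8, -8))
        ga = ProjectionGeometry(detector_shape=(3, 3), pixel_spacing=(4, 4))
        gl = ProjectionGeometry(detector_shape=(3, 3), pixel_spacing=(4, 4),
                                view=lat_view_transform(90.0))
        bad = DRRImage(np.ones((2, 2)), (4, 4))
        with pytest.raises(ValueError):
            perspective_projection_loss(vol, bad, bad, ga, gl)

    def test_total_generator_loss_weighting(self):
        assert total_generator_loss(1.0, 1.0, 1.0) == pytest.approx(20.1)
        assert total_generator_loss(0.0, 0.0, 0.0) == 0.0
        assert total_generator_loss(2.0, 2.0, 2.0) == \
            pytest.approx(2 * total_generator_loss(1.0, 1.0, 1.0))


class TestContrastAdjust:
    @pytest.fixture()
    def image(self, rng):
        return DRRImage(rng.uniform(0, 100, size=(8, 8)), (1, 1))

    def test_mid_is_identity_after_normalization(self, image):
        out = contrast_adjust(image, "mid")
        lo, hi = image.pixels.min(), image.pixels.max()
        np.testing.assert_allclose(out.pixels,
                                   (image.pixels - lo) / (hi - lo), atol=1e-12)

    @pytest.mark.parametrize("level", ["low", "mid", "high"])
    def test_monotone_order_preserved(self, image, level):
        out = contrast_adjust(image, level)
        order_in = np.argsort(image.pixels.ravel())
        order_out = np.argsort(out.pixels.ravel())
        np.testing.assert_array_equal(order_in, order_out)

    def test_low_and_high_differ_on_midtones(self):
        img = DRRImage(np.array([[0.0, 0.25, 1.0]]), (1, 1))
        low = contrast_adjust(img, "low").pixels[0, 1]
        high = contrast_adjust(img, "high").pixels[0, 1]
        assert low == pytest.approx(0.5)
        assert high == pytest.approx(0.0625)
        assert low > high

    def test_unknown_level_rejected(self, image):
        with pytest.raises(ValueError):
            contrast_adjust(image, "ultra")


class TestDRRIO:
    def test_png_sidecar_round_trip(self, tmp_path, rng):
        img = DRRImage(rng.uniform(0, 500, size=(16, 16)), (2, 2), view="AP")
        path = str(tmp_path / "drr.png")
        save_drr(img, path, ProjectionGeometry(), Pose6DoF())
        back = load_drr(path)
        assert back.view == "AP"
        # 16-bit quantization bounds the round-trip error
        assert np.max(np.abs(back.pixels - img.pixels)) < 500 / 65535 * 1.01
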