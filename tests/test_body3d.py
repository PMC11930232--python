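"""Body reconstruction: OT barycenters, meshing, Euler-Bernoulli bending."""

import numpy as np
import pytest

from escapeswim.body3d import (build_surface_mesh, deform_to_midline,
                               interpolate_stack, normalize_slices,
                               planar_motion_from_midlines, scale_to_length,
                               sinkhorn_barycenter)
from escapeswim.containers import SliceStack
from escapeswim.imaging import iou
from escapeswim.synthgen import make_slice_stack


def _disc(shape, r, center=None):
    H, W = shape
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    yy, xx = np.mgrid[:H, :W]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


class TestNormalizeSlices:
    def test_symmetric_slice_unchanged(self):
        d = _disc((33, 33), 9)
        st = normalize_slices([d])
        assert np.array_equal(st.images[0], d)

    def test_asymmetric_lobe_unioned_with_mirror(self):
        m = np.zeros((21, 21), bool)
        m[8:13, 3:10] = True
        st = normalize_slices([m])
        assert np.array_equal(st.images[0], m | m[:, ::-1])

    def test_grayscale_threshold_matches_brute_force(self):
        img = np.zeros((31, 31))
        img[10:20, 10:20] = 200.0
        st = normalize_slices([img])
        expected = (img > 100.0)
        expected = expected | expected[:, ::-1]
        assert st.images[0].sum() == expected.sum()

    def test_empty_slice_dropped_with_warning(self):
        d = _disc((21, 21), 6)
        with pytest.warns(UserWarning, match="dropped"):
            st = normalize_slices([d, np.zeros((21, 21), bool), d],
                                  positions_um=np.array([0.0, 10.0, 20.0]))
        assert st.n_slices == 2
        assert list(st.positions_um) == [0.0, 20.0]


class TestSinkhornBarycenter:
    def test_identity(self):
        d = _disc((64, 64), 12)
        out = sinkhorn_barycenter(d, d, 0.5)
        assert iou(out, d) >= 0.95

    def test_point_mass_midpoint(self):
        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        a[32, 10] = 1.0
        b[32, 54] = 1.0
        den = sinkhorn_barycenter(a, b, 0.5, return_density=True)
        peak = np.unravel_index(np.argmax(den), den.shape)
        assert peak == (32, 32)

    def test_weight_limits(self):
        a = _disc((48, 48), 10)
        b = np.roll(a, 8, axis=1)
        assert iou(sinkhorn_barycenter(a, b, 0.0), a) >= 0.9
        assert iou(sinkhorn_barycenter(a, b, 1.0), b) >= 0.9

    def test_disc_area_monotone(self):
        small = _disc((80, 80), 10)
        big = _disc((80, 80), 20)
        mid = sinkhorn_barycenter(small, big, 0.5)
        assert small.sum() < mid.sum() < big.sum()

    def test_invalid_inputs(self):
        d = _disc((16, 16), 4)
        with pytest.raises(ValueError):
            sinkhorn_barycenter(d, d, 1.5)
        with pytest.raises(ValueError):
            sinkhorn_barycenter(d, np.zeros((16, 16)), 0.5)


class TestInterpolateStack:
    def test_key_slices_reproduced_exactly(self):
        d1 = _disc((40, 40), 8)
        d2 = _disc((40, 40), 14)
        st = SliceStack(images=np.stack([d1, d2]),
                        positions_um=np.array([0.0, 100.0]), px_um=10.0)
        out = interpolate_stack(st, 50.0)
        assert np.array_equal(out.images[0], d1)
        assert np.array_equal(out.images[-1], d2)
        assert d1.sum() < out.images[1].sum() < d2.sum()

    def test_recovers_missing_slices(self, profile):
        full = make_slice_stack(profile, spacing_um=96.0, px_um=15.0)
        holey = make_slice_stack(profile, spacing_um=96.0, px_um=15.0,
                                 missing_fraction=0.3, seed=1)
        rec = interpolate_stack(holey, 96.0)
        assert rec.n_slices == full.n_slices
        ious = [iou(rec.images[i], full.images[i])
                for i in range(full.n_slices)]
        assert np.mean(ious) >= 0.9

    def test_spacing_larger_than_span_rejected(self):
        d = _disc((16, 16), 4)
        st = SliceStack(images=np.stack([d, d]),
                        positions_um=np.array([0.0, 10.0]), px_um=1.0)
        with pytest.raises(ValueError):
            interpolate_stack(st, 100.0)


@pytest.fixture(scope="module")
def cylinder():
    d = _disc((32, 32), 10)
    return SliceStack(images=np.stack([d] * 40),
                      positions_um=np.arange(40) * 10.0, px_um=10.0)


class TestSurfaceMesh:
    def test_cylinder_volume_and_area(self, cylinder):
        mesh = build_surface_mesh(cylinder, n_axial=40, n_circ=64)
        r_mm = np.sqrt(cylinder.images[0].sum() / np.pi) * 0.01
        L_mm = 0.39
        assert mesh.volume_mm3 == pytest.approx(
            np.pi * r_mm**2 * 0.40, rel=0.05)
        assert mesh.surface_area() == pytest.approx(
            2 * np.pi * r_mm * L_mm, rel=0.05)

    def test_marker_grid_shape_default(self, cylinder):
        mesh = build_surface_mesh(cylinder)
        assert (mesh.n_axial, mesh.n_circ) == (300, 180)

    def test_scaling_laws(self, cylinder):
        mesh = build_surface_mesh(cylinder, n_axial=20, n_circ=32)
        scaled = scale_to_length(mesh, 3.829)
        assert scaled.standard_length == pytest.approx(3.829)
        s = 3.829 / mesh.standard_length
        assert scaled.volume_mm3 == pytest.approx(mesh.volume_mm3 * s**3)
        assert scale_to_length(mesh, mesh.standard_length).volume_mm3 \
            == pytest.approx(mesh.volume_mm3)

    def test_disconnected_volume_rejected(self):
        d = _disc((32, 32), 8)
        blank = np.zeros_like(d)
        st = SliceStack(images=np.stack([d, blank, d]),
                        positions_um=np.arange(3) * 10.0, px_um=10.0)
        with pytest.raises(ValueError, match="connected"):
            build_surface_mesh(st, n_axial=3, n_circ=16)


@pytest.fixture(scope="module")
def mesh(profile):
    st = make_slice_stack(profile, spacing_um=192.0, px_um=20.0)
    m = build_surface_mesh(st, n_axial=40, n_circ=24)
    return scale_to_length(m, profile.standard_length)


class TestDeformToMidline:
    def test_straight_midline_constant_motion(self, mesh):
        L = mesh.standard_length
        straight = np.stack([np.linspace(0, L, 301), np.zeros(301)], 1)
        bm = deform_to_midline(mesh, [straight] * 6, dt=1e-4)
        assert np.abs(bm.u_tilde).max() == 0.0

    def test_rigid_rotation_removed(self, mesh):
        L = mesh.standard_length
        straight = np.stack([np.linspace(0, L, 301), np.zeros(301)], 1)
        a = np.deg2rad(8.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        frames = [straight, straight @ R.T, straight @ R.T @ R.T]
        bm = deform_to_midline(mesh, frames, dt=1e-4, mean_filter_s=0.0)
        drift = np.abs(bm.markers[1] - bm.markers[0]).max()
        assert drift < 0.02 * L

    def test_volume_preserved_under_bending(self, mesh):
        L = mesh.standard_length
        phi = np.deg2rad(80.0) * np.linspace(0, 1, 301) ** 2
        ds = L / 300
        bent = np.vstack([[0, 0], np.cumsum(
            np.stack([np.cos(phi), np.sin(phi)], 1)[:-1] * ds, axis=0)])
        straight = np.stack([np.linspace(0, L, 301), np.zeros(301)], 1)
        bm = deform_to_midline(mesh, [straight, bent], dt=1e-4,
                               mean_filter_s=0.0)
        # cross-sections are rigid in-plane: ring extents are preserved
        w0 = np.abs(bm.markers[0][..., 2]).max()
        w1 = np.abs(bm.markers[1][..., 2]).max()
        assert w1 == pytest.approx(w0, rel=0.03)

    def test_mean_filter_window_from_dt(self, mesh):
        L = mesh.standard_length
        straight = np.stack([np.linspace(0, L, 301), np.zeros(301)], 1)
        bm = deform_to_midline(mesh, [straight] * 12, dt=1e-4,
                               mean_filter_s=0.5e-3)
        assert bm.n_frames == 12  # window=5 frames, applied in place


class TestPlanarMotion:
    def test_area_matches_width_function(self, profile):
        L = profile.standard_length
        straight = np.stack([np.linspace(0, L, 301), np.zeros(301)], 1)
        pm = planar_motion_from_midlines([straight] * 5, profile.half_width,
                                         dt=1e-4)
        assert pm.polygon_area(0) == pytest.approx(
            profile.silhouette_area(), rel=0.02)

    def test_deformation_has_zero_net_angular_momentum(self, water_motion):
        w = water_motion.weights.reshape(-1)
        for i in (100, 300, 500):
            x = water_motion.interior[i].reshape(-1, 2)
            v = water_motion.interior_vel[i].reshape(-1, 2)
            L = (w * (x[:, 0] * v[:, 1] - x[:, 1] * v[:, 0])).sum()
            I = (w * (x**2).sum(axis=1)).sum()
            vmax = max(np.abs(v).max(), 1e-12)
            # residual rotation rate is a small fraction of the rate at
            # which the body would rotate if vmax were all rotational
            assert abs(L / I) < 0.05 * vmax / (
                0.5 * water_motion.standard_length)
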