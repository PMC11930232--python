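"""Midline extraction geometry and kinematic-descriptor contracts."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from escapeswim.containers import BinaryMask, RigidTrace
from escapeswim.imaging import segment_frame
from escapeswim.midline import (KinematicsSummary, Midline, MidlineError,
                                extract_midline, kinematic_descriptors,
                                midline_curvature, stage_window)


def _arc_midline(total_deg: float) -> Midline:
    """Polyline whose 299 joints each turn total/299: a uniform arc."""
    phi = np.deg2rad(np.linspace(0.0, total_deg, 300))
    steps = np.stack([np.cos(phi), np.sin(phi)], 1) / 300.0
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Midline(points=pts)


class TestMidlineCurvature:
    def test_straight_is_zero(self):
        mj, ht = midline_curvature(_arc_midline(0.0))
        assert mj == pytest.approx(0.0, abs=1e-9)
        assert ht == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("total", [40.0, -75.0, 180.0])
    def test_uniform_arc(self, total):
        mj, ht = midline_curvature(_arc_midline(total))
        assert ht == pytest.approx(total, rel=1e-6)
        assert mj == pytest.approx(total / 299.0, rel=1e-6)

    def test_mirrored_midline_negates_angles(self):
        m = _arc_midline(60.0)
        mirrored = Midline(points=m.points * np.array([1.0, -1.0]))
        mj, ht = midline_curvature(m)
        mjm, htm = midline_curvature(mirrored)
        assert mjm == pytest.approx(-mj)
        assert htm == pytest.approx(-ht)


class TestExtractMidline:
    def test_straight_rectangle(self):
        m = np.zeros((60, 220), bool)
        m[25:35, 20:200] = True
        ml = extract_midline(BinaryMask(m, 1.0))
        assert ml.length == pytest.approx(180.0, rel=0.02)
        rms = np.sqrt(np.mean((ml.points[:, 1]
                               - ml.points[:, 1].mean()) ** 2))
        assert rms < 1.0

    def test_symmetric_shape_midline_on_axis(self):
        yy, xx = np.mgrid[:80, :200]
        m = (np.abs(yy - 40) < 12 * np.exp(-((xx - 100) / 80.0) ** 2)) \
            & (xx > 20) & (xx < 180)
        ml = extract_midline(BinaryMask(m, 1.0))
        rms = np.sqrt(np.mean((ml.points[:, 1] - (80 - 1 - 40)) ** 2))
        assert rms < 1.0

    def test_bent_swimmer_close_to_ground_truth(self, frame_stack,
                                                kinematics, default_params):
        p = default_params
        W, H = p.image_size
        p0 = np.array([(W - 1) * p.pixel_scale / 2,
                       (H - 1) * p.pixel_scale / 2])
        for i in (60, 250, 450):
            mask = segment_frame(frame_stack.frames[i], 5.0, p.pixel_scale)
            ml = extract_midline(mask)
            a = np.deg2rad(kinematics.alpha[i])
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            gt = kinematics.midlines[i] @ R.T + p0 + kinematics.cm[i]
            d, _ = cKDTree(gt).query(ml.points)
            assert d.mean() / p.pixel_scale < 1.5

    def test_exact_segment_count(self, frame_stack):
        mask = segment_frame(frame_stack.frames[0], 5.0,
                             frame_stack.pixel_scale)
        ml = extract_midline(mask)
        assert ml.points.shape == (301, 2)


class TestKinematicDescriptors:
    @staticmethod
    def _trace(default_params, kinematics):
        return kinematics.head_tail_angle, default_params.dt

    def test_stationary_cm_zero_distance(self, kinematics, default_params):
        ht, dt = self._trace(default_params, kinematics)
        n = ht.size
        rigid = RigidTrace(t=np.arange(n) * dt, cm=np.zeros((n, 2)),
                           alpha=np.zeros(n))
        s = kinematic_descriptors(rigid, ht, dt)
        assert s.distance_traveled == 0.0
        assert s.mean_velocity == 0.0

    def test_constant_velocity_closed_form(self, kinematics, default_params):
        ht, dt = self._trace(default_params, kinematics)
        n = ht.size
        v = 37.0  # mm/s
        cm = np.stack([v * np.arange(n) * dt, np.zeros(n)], 1)
        rigid = RigidTrace(t=np.arange(n) * dt, cm=cm, alpha=np.zeros(n))
        s = kinematic_descriptors(rigid, ht, dt)
        assert s.mean_velocity == pytest.approx(v, rel=1e-6)
        assert s.distance_traveled == pytest.approx(
            v * s.total_duration_six_movements * 1e-3, rel=1e-6)

    def test_recovers_generator_frequency_and_amplitude(
            self, kinematics, default_params):
        ht, dt = self._trace(default_params, kinematics)
        n = ht.size
        rigid = RigidTrace(t=np.arange(n) * dt, cm=kinematics.cm,
                           alpha=kinematics.alpha)
        s = kinematic_descriptors(rigid, ht, dt)
        assert s.tail_beat_frequency == pytest.approx(
            default_params.beat_frequency, rel=0.05)
        assert s.fast_swim_beat_amplitude == pytest.approx(
            default_params.fastswim_amplitude, rel=0.05)
        assert s.max_head_tail_angle == pytest.approx(
            default_params.cbend_amplitude, rel=0.02)

    def test_too_few_maxima_raises_with_count(self):
        ht = 20.0 * np.sin(2 * np.pi * 5.0 * np.arange(200) * 1e-3)
        rigid = RigidTrace(t=np.arange(200) * 1e-3, cm=np.zeros((200, 2)),
                           alpha=np.zeros(200))
        with pytest.raises(MidlineError, match=r"\d"):
            kinematic_descriptors(rigid, ht, 1e-3)


class TestStageWindow:
    def test_window_ends_after_sixth_maximum(self, kinematics,
                                             default_params):
        peaks, t_end = stage_window(kinematics.head_tail_angle,
                                    default_params.dt)
        assert peaks.size == 6
        assert t_end > peaks[5] * default_params.dt

    def test_distance_invariant_to_trajectory_rotation(self):
        rng = np.random.default_rng(2)
        steps = rng.normal(0, 0.1, (50, 2))
        cm = np.cumsum(steps, axis=0)
        a = np.deg2rad(33.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        t = np.arange(50) * 1e-3
        d0 = RigidTrace(t=t, cm=cm, alpha=np.zeros(50)).distance_traveled()
        d1 = RigidTrace(t=t, cm=cm @ R.T,
                        alpha=np.zeros(50)).distance_traveled()
        assert d0 == pytest.approx(d1, rel=1e-12)


def test_midline_validation_rejects_uneven_segments():
    pts = np.stack([np.linspace(0, 1, 301) ** 2, np.zeros(301)], 1)
    pts[0, 0] = -1e-6
    with pytest.raises(ValueError):
        Midline(points=pts)
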