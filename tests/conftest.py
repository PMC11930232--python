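"""Shared fixtures: one synthetic escape sequence reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from escapeswim import synthgen
from escapeswim.body3d import planar_motion_from_midlines
from escapeswim.containers import FrameStack


@pytest.fixture(scope="session")
def default_params() -> synthgen.CStartParams:
    return synthgen.CStartParams()


@pytest.fixture(scope="session")
def profile() -> synthgen.BodyProfile:
    return synthgen.default_profile()


@pytest.fixture(scope="session")
def kinematics(default_params, profile):
    return synthgen.make_cstart_kinematics(default_params, profile)


@pytest.fixture(scope="session")
def frame_stack(kinematics, profile, default_params) -> FrameStack:
    return synthgen.rasterize_swimmer(kinematics, profile, default_params)


@pytest.fixture(scope="session")
def subsampled_stack(frame_stack) -> FrameStack:
    """Every 4th frame -- enough temporal structure at a quarter the cost."""
    return FrameStack(frames=frame_stack.frames[::4].copy(),
                      dt=frame_stack.dt * 4,
                      pixel_scale=frame_stack.pixel_scale,
                      ground_truth_masks=frame_stack.ground_truth_masks[::4])


@pytest.fixture(scope="session")
def water_motion(kinematics, profile, default_params):
    """Planar body motion of the default C-start (ground-truth midlines)."""
    return planar_motion_from_midlines(
        list(kinematics.midlines), profile.half_width,
        dt=default_params.dt, head_tail_angle=kinematics.head_tail_angle)


@pytest.fixture(scope="session")
def small_slice_stack(profile):
    return synthgen.make_slice_stack(profile, spacing_um=96.0, px_um=15.0)
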