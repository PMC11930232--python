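"""Shared data containers for the escape-swim pipeline.

Conventions used throughout the package (stated once, used everywhere):

* physical coordinates ``(x, y)`` in mm, with ``y`` increasing upward;
* image row/col map to physical ``y``/``x`` with row 0 at the top, so
  ``y = (H - 1 - row) * pixel_scale`` and ``x = col * pixel_scale``;
* angles are in degrees, counterclockwise-positive from +x;
* pixel indices are 0-based and a pixel's coordinate is its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """An ordered stack of grayscale movie frames with calibration.

    Parameters
    ----------
    frames : (n_frames, H, W) array
        Grayscale images, intensity in [0, 255].
    dt : float
        Inter-frame interval in seconds (1 / frame rate).
    pixel_scale : float
        mm per pixel.
    ground_truth_masks : (n_frames, H, W) bool array, optional
        Present only on synthetic stacks; the rasterizer's own silhouettes.
    """

    frames: np.ndarray
    dt: float
    pixel_scale: float
    ground_truth_masks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("FrameStack needs >= 2 frames of identical shape")
        if self.dt <= 0 or self.pixel_scale <= 0:
            raise ValueError("dt and pixel_scale must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class BinaryMask:
    """A segmented silhouette with calibration inherited from its FrameStack."""

    mask: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_scale**2


@dataclass
class RigidTrace:
    """Per-frame rigid motion: center of mass (mm) and body rotation (deg)."""

    t: np.ndarray          # (n,) seconds
    cm: np.ndarray         # (n, 2) mm, (x, y)
    alpha: np.ndarray      # (n,) degrees, continuous (unwrapped)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not (np.all(np.isfinite(self.cm)) and np.all(np.isfinite(self.alpha))):
            raise ValueError("rigid trace must be finite")
        if self.alpha.size > 1 and np.any(np.abs(np.diff(self.alpha)) >= 90.0):
            raise ValueError("per-frame rotation jump >= 90 deg violates the "
                             "differential-angle scheme precondition")

    def distance_traveled(self) -> float:
        """Cumulative path length of the center of mass, mm."""
        return float(np.sum(np.hypot(*np.diff(self.cm, axis=0).T)))


@dataclass
class SliceStack:
    """Ordered binary transverse cross-sections along the body axis.

    ``positions_um`` carries each slice's axial station so that stacks with
    missing (removed) slices remain well defined.
    """

    images: np.ndarray        # (n, H, W) bool
    positions_um: np.ndarray  # (n,) axial positions, micrometers
    px_um: float              # in-plane pixel size, micrometers

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=bool)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.images.shape[0] != self.positions_um.size:
            raise ValueError("one axial position per slice required")
        if self.px_um <= 0:
            raise ValueError("px_um must be positive")

    @property
    def n_slices(self) -> int:
        return int(self.images.shape[0])

    @property
    def spacing_um(self) -> float:
        """Median inter-slice spacing (exact for uniform stacks)."""
        if self.n_slices < 2:
            raise ValueError("spacing undefined for a single slice")
        return float(np.median(np.diff(self.positions_um)))
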