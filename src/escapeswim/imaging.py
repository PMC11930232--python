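"""Segmentation and rigid-motion isolation of silhouette movies.

The isolation stage decomposes each segmented fish silhouette into a rigid
part (center-of-mass translation plus a body rotation ``alpha`` tracked with a
differential second-moment scheme) and the pure body deformation that remains
after both are subtracted. Rigid transforms are applied to sub-pixel boundary
contours, not resampled images, so the decomposition is lossless up to a
single rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.signal import savgol_filter
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .containers import BinaryMask, FrameStack, RigidTrace

__all__ = [
    "SegmentationError",
    "SmoothingConfig",
    "IsolatedBodyFrames",
    "segment_frame",
    "center_of_mass",
    "body_angle",
    "procrustes_isolate",
]


class SegmentationError(RuntimeError):
    pass


@dataclass
class SmoothingConfig:
    """Savitzky-Golay smoothing of the rigid traces (window in frames)."""

    window: int = 11
    order: int = 3


def segment_frame(image: np.ndarray, percentile: float = 5.0,
                  pixel_scale: float = 1.0) -> BinaryMask:
    """Segment the fish as pixels strictly below the lower intensity percentile.

    The largest connected component is kept (discarding isolated noise
    specks) and its holes are filled. Raises :class:`SegmentationError` when
    nothing remains (e.g. a uniform-intensity frame).
    """
    if not 0.0 < percentile < 50.0:
        raise ValueError("percentile must be in (0, 50)")
    image = np.asarray(image, dtype=float)
    threshold = np.percentile(image, percentile)
    raw = image < threshold
    if not raw.any():
        raise SegmentationError("no foreground after segmentation cleanup")
    labels = measure.label(raw)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return BinaryMask(mask=binary_fill_holes(labels == largest),
                      pixel_scale=pixel_scale)


def _pixel_coords(mask: np.ndarray, pixel_scale: float) -> np.ndarray:
    """Physical (x, y) coordinates (mm) of foreground pixel centers."""
    rows, cols = np.nonzero(mask)
    H = mask.shape[0]
    return np.stack([cols * pixel_scale, (H - 1 - rows) * pixel_scale], axis=1)


def center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Area centroid of the silhouette in calibrated (x, y) mm."""
    if not mask.mask.any():
        raise SegmentationError("empty mask has no center of mass")
    return _pixel_coords(mask.mask, mask.pixel_scale).mean(axis=0)


def body_angle(mask: BinaryMask, previous_alpha: float = 0.0,
               rel_tol: float = 0.05) -> tuple[float, bool]:
    """Orientation (deg) of the silhouette's principal second-moment axis.

    The principal axis is only defined modulo 180 deg; the branch closest to
    ``previous_alpha`` is returned (the differential scheme: equivalent to
    derotating the silhouette by the previous angle and measuring the small
    residual). An isotropic silhouette (principal moments equal within
    ``rel_tol``) returns ``previous_alpha`` with the degeneracy flag set.
    """
    pts = _pixel_coords(mask.mask, mask.pixel_scale)
    if pts.shape[0] == 0:
        raise SegmentationError("empty mask has no orientation")
    r = pts - pts.mean(axis=0)
    cov = r.T @ r / r.shape[0]
    # pixel footprint keeps the tensor well conditioned for thin shapes
    cov += np.eye(2) * mask.pixel_scale**2 / 12.0
    evals = np.linalg.eigvalsh(cov)
    if evals[1] - evals[0] <= rel_tol * evals[1]:
        return float(previous_alpha), True
    ang = np.rad2deg(0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1]))
    k = np.round((previous_alpha - ang) / 180.0)
    return float(ang + 180.0 * k), False


def _mask_contour(mask: np.ndarray, pixel_scale: float) -> np.ndarray:
    """Longest sub-pixel boundary contour of a mask, in physical (x, y) mm."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no boundary contour")
    c = max(contours, key=len)
    H = mask.shape[0]
    return np.stack([c[:, 1] * pixel_scale,
                     (H - 1 - c[:, 0]) * pixel_scale], axis=1)


def _rasterize_contour(contour_mm: np.ndarray, shape: tuple[int, int],
                       pixel_scale: float) -> np.ndarray:
    H, W = shape
    rows = (H - 1) - contour_mm[:, 1] / pixel_scale
    cols = contour_mm[:, 0] / pixel_scale
    rr, cc = draw_polygon(rows, cols, shape=(H, W))
    out = np.zeros((H, W), dtype=bool)
    out[rr, cc] = True
    return out


def _rot(a_deg: float) -> np.ndarray:
    a = np.deg2rad(a_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


@dataclass
class IsolatedBodyFrames:
    """Body movement with translation and rotation removed.

    ``contours`` are sub-pixel boundary polygons in the body frame (mm,
    centroid at the origin); ``masks`` are their rasterizations on a canvas
    whose center pixel is the origin. ``rigid`` holds the removed motion, so
    that ``recompose()`` reproduces the input silhouettes.
    """

    contours: list[np.ndarray]
    rigid: RigidTrace
    pixel_scale: float
    canvas_shape: tuple[int, int]
    masks: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.masks is None:
            H, W = self.canvas_shape
            center = np.array([(W - 1) / 2.0, (H - 1) / 2.0]) * self.pixel_scale
            self.masks = np.stack([
                _rasterize_contour(c + center, self.canvas_shape,
                                   self.pixel_scale)
                for c in self.contours
            ])

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    def binary_masks(self) -> list[BinaryMask]:
        return [BinaryMask(m, self.pixel_scale) for m in self.masks]

    def recompose(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Re-apply the removed rigid motion; returns (n, H, W) bool masks."""
        if shape is None:
            shape = self.canvas_shape
        out = np.zeros((self.n_frames, *shape), dtype=bool)
        for i, c in enumerate(self.contours):
            world = c @ _rot(self.rigid.alpha[i]).T + self.rigid.cm[i]
            out[i] = _rasterize_contour(world, shape, self.pixel_scale)
        return out


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def procrustes_isolate(
    stack: FrameStack,
    percentile: float = 5.0,
    smoothing: SmoothingConfig | None = None,
) -> IsolatedBodyFrames:
    """Subtract translational and rotational motion from a silhouette movie.

    Segments every frame, tracks the center of mass and the body rotation
    ``alpha`` with the differential second-moment scheme, temporally smooths
    both traces, and derotates/centers each frame's sub-pixel contour. The
    first frame is assumed to show the fish before motion onset.
    """
    if smoothing is None:
        smoothing = SmoothingConfig()
    n = stack.n_frames
    t = np.arange(n) * stack.dt
    cms = np.empty((n, 2))
    alphas = np.empty(n)
    contours_world: list[np.ndarray] = []
    prev = 0.0
    for i in range(n):
        mask = segment_frame(stack.frames[i], percentile, stack.pixel_scale)
        cms[i] = center_of_mass(mask)
        ang, _degen = body_angle(mask, previous_alpha=prev)
        if i > 0 and abs(ang - alphas[i - 1]) >= 90.0:
            raise SegmentationError(
                f"rotation jump >= 90 deg between frames {i - 1} and {i}")
        alphas[i] = ang
        prev = ang
        contours_world.append(_mask_contour(mask.mask, stack.pixel_scale))

    if n > smoothing.window > smoothing.order:
        cm_s = savgol_filter(cms, smoothing.window, smoothing.order, axis=0)
        al_s = savgol_filter(alphas, smoothing.window, smoothing.order)
    else:
        cm_s, al_s = cms, alphas

    contours_body = [
        (c - cm_s[i]) @ _rot(-al_s[i]).T
        for i, c in enumerate(contours_world)
    ]
    rigid = RigidTrace(t=t, cm=cm_s, alpha=al_s)
    return IsolatedBodyFrames(contours=contours_body, rigid=rigid,
                              pixel_scale=stack.pixel_scale,
                              canvas_shape=stack.frames.shape[1:])
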