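"""Midline extraction and kinematic descriptors of the escape swim.

The midline is the anteroposterior body axis, discretized into 300 equal
arclength segments (301 points) from snout to tail tip. The mean of the
signed angles between consecutive segments is the "midline curvature"
indicator of bending amplitude; the head-tail angle is their sum. Descriptors
of the six-movement escape (C-bend, counterbend, four fast-swim beats) are
located from the ordered maxima of the absolute head-tail angle trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import skeletonize

from .containers import BinaryMask, RigidTrace

__all__ = [
    "Midline",
    "MidlineError",
    "KinematicsSummary",
    "extract_midline",
    "midline_curvature",
    "kinematic_descriptors",
    "stage_window",
]

N_SEGMENTS = 300


class MidlineError(RuntimeError):
    pass


@dataclass
class Midline:
    """301 ordered points (mm) from head to tail; 300 segments."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_SEGMENTS + 1, 2):
            raise ValueError(f"midline must have {N_SEGMENTS + 1} points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if seg.min() <= 0:
            raise ValueError("midline arclength must be monotone")
        if (seg.max() - seg.min()) / seg.mean() > 0.05:
            raise ValueError("segment lengths must be equal within 5%")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0),
                                    axis=1).sum())

    def turning_angles(self) -> np.ndarray:
        """Signed angle (deg) between consecutive segments, head to tail.

        Positive means a leftward bend when walking from head to tail.
        """
        d = np.diff(self.points, axis=0)
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        dot = (d[:-1] * d[1:]).sum(axis=1)
        return np.rad2deg(np.arctan2(cross, dot))


def _skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Longest path through the morphological skeleton (pixel coordinates).

    The skeleton is treated as an 8-connected graph; the path between the two
    most distant endpoints (double breadth-first search with Euclidean step
    weights) prunes side branches.
    """
    skel = skeletonize(mask)
    pix = np.argwhere(skel)
    if pix.shape[0] < 2:
        raise MidlineError("skeleton too short")
    index = {tuple(p): i for i, p in enumerate(pix)}
    nbrs: list[list[tuple[int, float]]] = [[] for _ in range(pix.shape[0])]
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]
    for i, (r, c) in enumerate(pix):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append((j, float(np.hypot(dr, dc))))

    def farthest(src: int) -> tuple[int, np.ndarray, np.ndarray]:
        import heapq
        dist = np.full(pix.shape[0], np.inf)
        prev = np.full(pix.shape[0], -1, dtype=int)
        dist[src] = 0.0
        heap = [(0.0, src)]
        while heap:
            d, i = heapq.heappop(heap)
            if d > dist[i]:
                continue
            for j, w in nbrs[i]:
                nd = d + w
                if nd < dist[j]:
                    dist[j] = nd
                    prev[j] = i
                    heapq.heappush(heap, (nd, j))
        dist[np.isinf(dist)] = -1.0
        return int(np.argmax(dist)), dist, prev

    a, _, _ = farthest(0)
    b, _, prev = farthest(a)
    path = [b]
    while prev[path[-1]] != -1:
        path.append(int(prev[path[-1]]))
    if len(path) < 2:
        raise MidlineError("skeleton branching irresolvable")
    return pix[path[::-1]]


def _subpixel_contour(mask: np.ndarray) -> np.ndarray:
    """Longest closed sub-pixel boundary contour, (row, col), open-ended."""
    from skimage import measure
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise MidlineError("mask has no boundary contour")
    c = max(contours, key=len)
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    return c


def _normal_midpoint_offsets(pts: np.ndarray, nrm: np.ndarray,
                             cont: np.ndarray, tmax: float = 14.0,
                             clip: float = 2.0) -> np.ndarray:
    """Signed offset of each point to the midpoint of its two body sides.

    Intersects the line through ``pts[i]`` along ``nrm[i]`` with the closed
    contour polyline and midpoints the nearest crossing on each side. Points
    without a crossing within ``tmax`` px on both sides keep a zero offset.
    """
    A = cont
    d = np.roll(cont, -1, axis=0) - cont
    det = nrm[:, None, 0] * (-d[None, :, 1]) - nrm[:, None, 1] * (-d[None, :, 0])
    rhs = A[None, :, :] - pts[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(det) < 1e-12, np.nan,
                     (rhs[..., 0] * (-d[None, :, 1])
                      - rhs[..., 1] * (-d[None, :, 0])) / det)
        u = np.where(np.abs(det) < 1e-12, np.nan,
                     (nrm[:, None, 0] * rhs[..., 1]
                      - nrm[:, None, 1] * rhs[..., 0]) / det)
    valid = (u >= 0) & (u < 1) & np.isfinite(t)
    tpos = np.where(valid & (t > 0), t, np.inf).min(axis=1)
    tneg = np.where(valid & (t < 0), -t, np.inf).min(axis=1)
    ok = (tpos < tmax) & (tneg < tmax)
    off = np.zeros(pts.shape[0])
    off[ok] = (tpos[ok] - tneg[ok]) / 2.0
    return np.clip(off, -clip, clip)


def _ray_to_contour(origin: np.ndarray, direction: np.ndarray,
                    cont: np.ndarray) -> float | None:
    """Distance along a ray from ``origin`` to its first contour crossing."""
    d = direction / max(np.linalg.norm(direction), 1e-12)
    seg = np.roll(cont, -1, axis=0) - cont
    det = d[0] * (-seg[:, 1]) - d[1] * (-seg[:, 0])
    rhs = cont - origin
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(det) < 1e-12, np.nan,
                     (rhs[:, 0] * (-seg[:, 1]) - rhs[:, 1] * (-seg[:, 0])) / det)
        u = np.where(np.abs(det) < 1e-12, np.nan,
                     (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / det)
    ok = (u >= 0) & (u < 1) & (t > 0) & np.isfinite(t)
    if not ok.any():
        return None
    return float(t[ok].min())


def _savgol_path(pts: np.ndarray, window: int, order: int = 2) -> np.ndarray:
    from scipy.signal import savgol_filter
    n = pts.shape[0]
    w = min(window, n - 1 if (n - 1) % 2 else n - 2)
    if w <= order:
        return pts
    return savgol_filter(pts, w, order, axis=0)


def extract_midline(mask: BinaryMask,
                    previous: Midline | None = None) -> Midline:
    """Extract the snout-to-tail midline of a silhouette.

    The morphological skeleton's longest path seeds the midline. Because the
    skeleton forks inside the wide head and its longest branch hooks toward a
    head corner, the path is cut at the head's width maximum and later
    extended straight through the (nearly rigid) head to the snout tip. The
    retained path is refined by midpointing sub-pixel contour crossings along
    the local normal, smoothed along arclength, extended to both silhouette
    tips, and resampled to 301 equal-arclength points. The head end is the
    end with the larger local body width; across frames the orientation is
    continued by nearest-end matching with ``previous``.
    """
    m = mask.mask
    path = _skeleton_path(m).astype(float)
    if path.shape[0] < 8:
        raise MidlineError("midline path too short to resample")
    cont = _subpixel_contour(m)

    # head = wider end; reorder head-first, then cut the head-blob hook
    dist = ndimage.distance_transform_edt(m)
    r = np.clip(np.round(path[:, 0]).astype(int), 0, m.shape[0] - 1)
    c = np.clip(np.round(path[:, 1]).astype(int), 0, m.shape[1] - 1)
    w = dist[r, c]
    k = max(2, len(path) // 5)
    if w[:k].mean() < w[-k:].mean():
        path, w = path[::-1], w[::-1]
    n_head = max(2, len(path) // 3)
    i_cut = int(np.argmax(w[:n_head]))
    path = path[i_cut:]

    # coarse equal-arclength resampling (~2 px)
    s = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))]
    n = max(int(s[-1] / 2.0), 15)
    t = np.linspace(0.0, s[-1], n)
    pts = np.stack([np.interp(t, s, path[:, 0]),
                    np.interp(t, s, path[:, 1])], axis=1)
    pts = _savgol_path(pts, 9)

    # iterative refinement to the transverse body center
    for _ in range(3):
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        pts = pts + _normal_midpoint_offsets(pts, nrm, cont)[:, None] * nrm
        pts = _savgol_path(pts, 15)
    pts = pts[1:-1]

    # extend both ends to the silhouette tips along the local direction
    pieces = [pts]
    for idx, inner in ((0, min(3, len(pts) - 1)), (-1, max(-4, -len(pts)))):
        d = pts[idx] - pts[inner]
        L = _ray_to_contour(pts[idx], d, cont)
        if L is not None and L > 0.3:
            d = d / np.linalg.norm(d)
            steps = np.linspace(0.25, 1.0, max(2, int(L)))
            ext = pts[idx] + steps[:, None] * L * d[None, :]
            if idx == 0:
                pieces.insert(0, ext[::-1])
            else:
                pieces.append(ext)
    full = np.vstack(pieces)
    keep = np.r_[True, np.linalg.norm(np.diff(full, axis=0), axis=1) > 1e-9]
    full = full[keep]

    # equal-arclength resampling directly on the smoothed polyline (a final
    # spline fit would re-introduce end-tangent wiggle)
    ds = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(full, axis=0), axis=1))]
    targets = np.linspace(0.0, ds[-1], N_SEGMENTS + 1)
    rows = np.interp(targets, ds, full[:, 0])
    cols = np.interp(targets, ds, full[:, 1])

    H = m.shape[0]
    out = np.stack([cols * mask.pixel_scale,
                    (H - 1 - rows) * mask.pixel_scale], axis=1)
    if previous is not None:
        # nearest-end matching wins over the width cue for continuity
        if (np.linalg.norm(out[-1] - previous.points[0])
                < np.linalg.norm(out[0] - previous.points[0])):
            out = out[::-1]
    return Midline(points=out)


def midline_curvature(m: Midline) -> tuple[float, float]:
    """(mean joint angle, head-tail angle), both in degrees.

    The mean of the signed turning angles over all joints is the midline
    curvature indicator; their sum is the head-to-tail angle (supporting
    totals beyond 180 degrees).
    """
    turn = m.turning_angles()
    return float(turn.mean()), float(turn.sum())


@dataclass
class KinematicsSummary:
    """Escape-swim descriptors over the six-movement window."""

    distance_traveled: float           # mm, cumulative cm path
    fast_swim_velocity: float          # mm/s, mean speed during fast swimming
    rotation_amplitude: float          # deg, mean of |alpha| local maxima
    tail_beat_frequency: float         # Hz, full undulation cycles / s
    max_head_tail_angle: float         # deg
    fast_swim_beat_amplitude: float    # deg, mean |head-tail| at beat peaks
    total_duration_six_movements: float  # ms
    mean_velocity: float               # mm/s, distance / duration


def _headtail_peaks(curvature_trace: np.ndarray, dt: float,
                    prominence: float, min_separation_s: float) -> np.ndarray:
    distance = max(1, int(round(min_separation_s / dt)))
    peaks, _ = find_peaks(np.abs(np.asarray(curvature_trace, dtype=float)),
                          prominence=prominence, distance=distance)
    return peaks


def stage_window(curvature_trace: np.ndarray, dt: float,
                 prominence: float = 10.0,
                 min_separation_s: float = 2e-3) -> tuple[np.ndarray, float]:
    """Locate the six movement maxima and the end of the analysis window.

    Returns the peak indices (C-bend, counterbend, four fast-swim beats) and
    the window end time: the sixth maximum plus half a beat period, where the
    beat period is the mean interval between the fast-swim maxima.
    """
    peaks = _headtail_peaks(curvature_trace, dt, prominence, min_separation_s)
    if peaks.size < 6:
        raise MidlineError(
            f"expected >= 6 curvature maxima, found {peaks.size}")
    peaks = peaks[:6]
    beat_interval = float(np.mean(np.diff(peaks[2:6]))) * dt
    t_end = peaks[5] * dt + 0.5 * beat_interval
    return peaks, t_end


def kinematic_descriptors(
    rigid: RigidTrace,
    curvature_trace: np.ndarray,
    dt: float,
    prominence: float = 10.0,
    min_separation_s: float = 2e-3,
) -> KinematicsSummary:
    """Compute all summary descriptors from the rigid trace and the
    head-tail-angle trace.

    Stage boundaries come from the ordered |head-tail angle| maxima (first =
    C-bend, second = counterbend, third through sixth = fast-swim beats). The
    tail-beat frequency is the inverse of twice the mean inter-peak interval
    during fast swimming (two |angle| maxima per undulation cycle); the
    fast-swim velocity is the mean center-of-mass speed from the
    counterbend/fast-swim transition to the window end.
    """
    curvature_trace = np.asarray(curvature_trace, dtype=float)
    peaks, t_end = stage_window(curvature_trace, dt, prominence,
                                min_separation_s)
    n = curvature_trace.size
    i_end = min(n - 1, int(round(t_end / dt)))

    step = np.linalg.norm(np.diff(rigid.cm, axis=0), axis=1)
    distance = float(step[:i_end].sum())
    duration_s = i_end * dt

    beat_interval = float(np.mean(np.diff(peaks[2:6]))) * dt
    freq = 1.0 / (2.0 * beat_interval)

    i_fast = (peaks[1] + peaks[2]) // 2
    fast_dist = float(step[i_fast:i_end].sum())
    fast_vel = fast_dist / ((i_end - i_fast) * dt) if i_end > i_fast else 0.0

    a = np.abs(rigid.alpha - rigid.alpha[0])
    a_peaks, _ = find_peaks(a[: i_end + 1])
    rot_amp = float(a[a_peaks].mean()) if a_peaks.size else float(a.max())

    return KinematicsSummary(
        distance_traveled=distance,
        fast_swim_velocity=fast_vel,
        rotation_amplitude=rot_amp,
        tail_beat_frequency=freq,
        max_head_tail_angle=float(np.abs(curvature_trace).max()),
        fast_swim_beat_amplitude=float(
            np.abs(curvature_trace[peaks[2:6]]).mean()),
        total_duration_six_movements=duration_s * 1e3,
        mean_velocity=distance / duration_s if duration_s > 0 else 0.0,
    )
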