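"""Synthetic C-start escape-swim generator.

Produces midline kinematics with the stereotyped three-stage structure of the
larval zebrafish fast-start (a high-amplitude C-bend, a counterbend, then a
bout of fast swimming), rasterizes them into high-speed silhouette movies with
a superposed rigid motion, and emits transverse cross-section stacks of the
body. Every output carries its ground truth (curvature trace, rigid motion,
silhouette masks) so that the downstream recovery stages can be tested without
any experimental recording.

The functional form of the midline wave is a smooth stand-in chosen for
testability, not a measured kinematic: the head-tail angle trace realizes the
stage amplitudes and the beat frequency exactly, with bending distributed
posteriorly along the body and a traveling phase during fast swimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d

from .containers import FrameStack, SliceStack

__all__ = [
    "CStartParams",
    "BodyProfile",
    "MidlineKinematics",
    "GenerationError",
    "default_profile",
    "make_cstart_kinematics",
    "rasterize_swimmer",
    "make_slice_stack",
]


class GenerationError(RuntimeError):
    pass


@dataclass
class CStartParams:
    """Parameters of a synthetic C-start escape sequence.

    Defaults emulate the acquisition used for larval escape recordings:
    10,000 frames per second over a 512 x 420 px window covering about
    13.0 x 10.7 mm^2, a C-bend of ~11 ms followed by a ~10 ms counterbend and
    four fast-swimming tail-beats (two full undulation cycles).
    """

    frame_rate: float = 10_000.0          # frames / s
    n_fast_beats: int = 4                 # tail-beats (half-cycles) of fast swim
    beat_frequency: float = 60.0          # Hz, full undulation cycles / s
    cbend_amplitude: float = 120.0        # deg, peak head-tail angle of C-bend
    counterbend_amplitude: float = 80.0   # deg
    fastswim_amplitude: float = 40.0      # deg, head-tail angle amplitude
    stage_durations: tuple[float, float, float] | None = None  # ms per stage
    superposed_translation: tuple[float, float] = (40.0, 15.0)  # mm / s
    superposed_rotation: float = 800.0    # deg / s
    pixel_scale: float = 13.0 / 512       # mm / px
    image_size: tuple[int, int] = (512, 420)  # (width, height) px
    noise_level: float = 0.02             # fraction of intensity range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.beat_frequency <= 0:
            raise ValueError("beat_frequency must be positive")
        if self.n_fast_beats < 1:
            raise ValueError("need at least one fast-swim beat")
        for a in (self.cbend_amplitude, self.counterbend_amplitude,
                  self.fastswim_amplitude):
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
        if self.stage_durations is None:
            # fast-swim duration follows from the beat count and frequency:
            # one beat is half an undulation cycle
            fast_ms = 1000.0 * self.n_fast_beats / (2.0 * self.beat_frequency)
            self.stage_durations = (11.0, 10.0, fast_ms)
        if any(d <= 0 for d in self.stage_durations):
            raise ValueError("stage durations must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def total_duration_ms(self) -> float:
        return float(sum(self.stage_durations))


@dataclass
class BodyProfile:
    """Axial body profile of the eleutheroembryo.

    Half-width and half-height are tabulated as functions of arclength from
    the snout; both vanish at the ends and are bilaterally symmetric by
    construction. ``finfold_extent`` is the additional dorsoventral extent of
    the median fin fold over the posterior body.
    """

    standard_length: float                 # mm, snout to end of vertebral column
    s_table: np.ndarray                    # (k,) arclength stations, mm
    half_width_table: np.ndarray           # (k,) mm
    half_height_table: np.ndarray          # (k,) mm
    finfold_extent: float = 0.25           # mm

    def __post_init__(self) -> None:
        self.s_table = np.asarray(self.s_table, dtype=float)
        self.half_width_table = np.asarray(self.half_width_table, dtype=float)
        self.half_height_table = np.asarray(self.half_height_table, dtype=float)
        if np.any(self.half_width_table < 0) or np.any(self.half_height_table < 0):
            raise ValueError("profile widths must be nonnegative")
        if self.half_width_table[0] > 1e-9 or self.half_width_table[-1] > 1e-9:
            raise ValueError("half-width must vanish at both ends")
        self._w = interp1d(self.s_table, self.half_width_table, kind="cubic",
                           bounds_error=False, fill_value=0.0)
        self._h = interp1d(self.s_table, self.half_height_table, kind="cubic",
                           bounds_error=False, fill_value=0.0)

    def half_width(self, s: np.ndarray) -> np.ndarray:
        """Half-width (lateral) at arclength s [mm]."""
        return np.clip(self._w(s), 0.0, None)

    def half_height(self, s: np.ndarray) -> np.ndarray:
        """Half-height (dorsoventral, without fin fold) at arclength s [mm]."""
        return np.clip(self._h(s), 0.0, None)

    def silhouette_area(self) -> float:
        """Analytic dorsal-silhouette area of the straight body, mm^2."""
        s = np.linspace(0.0, self.standard_length, 2001)
        return float(np.trapezoid(2.0 * self.half_width(s), s))


def default_profile(standard_length: float = 3.829) -> BodyProfile:
    """Reference larval body profile at the standard length of 3.829 mm.

    The width law places the widest section (half-width 0.25 mm) near the
    yolk/head region at ~18% of the body length and tapers smoothly to the
    tail; the height law peaks at 0.311 mm half-height (0.622 mm body height
    at the swim-bladder level).
    """
    L = float(standard_length)
    s = np.linspace(0.0, L, 121)
    x = s / L
    # head-bulged, tail-tapered width law; forced to vanish at both ends
    a = 0.18
    w = 0.25 * np.power((x / a) * np.exp(1.0 - x / a), 0.7, where=x > 0,
                        out=np.zeros_like(x))
    w *= np.sqrt(np.clip(1.0 - x**8, 0.0, None))
    w[0] = w[-1] = 0.0
    b = 0.25
    h = 0.311 * np.power((x / b) * np.exp(1.0 - x / b), 0.8, where=x > 0,
                         out=np.zeros_like(x))
    h *= np.sqrt(np.clip(1.0 - x**8, 0.0, None))
    h[0] = h[-1] = 0.0
    return BodyProfile(standard_length=L, s_table=s, half_width_table=w,
                       half_height_table=h, finfold_extent=0.25)


@dataclass
class MidlineKinematics:
    """Per-frame midlines in the body frame plus ground-truth traces.

    The body frame is normalized per frame so that the width-weighted
    silhouette centroid sits at the origin and the silhouette's principal
    second-moment axis is at 0 degrees (continuously tracked) -- the same
    convention the rigid-motion isolation stage converges to. The ground-truth
    rigid motion of the rendered movie is then exactly the superposed one.
    """

    t: np.ndarray                 # (n,) s
    midlines: np.ndarray          # (n, 301, 2) mm, body frame, head first
    head_tail_angle: np.ndarray   # (n,) deg, ground truth
    mean_joint_angle: np.ndarray  # (n,) deg, ground truth curvature indicator
    cm: np.ndarray                # (n, 2) mm, ground-truth rigid translation
    alpha: np.ndarray             # (n,) deg, ground-truth rigid rotation
    beat_frequency: float         # Hz, ground truth
    params: CStartParams = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return int(self.t.size)


_FAST_RAMP_S = 3e-3  # smoothstep onset of the fast-swim wave, s


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _headtail_angle_trace(params: CStartParams, t: np.ndarray) -> np.ndarray:
    """Head-tail angle (deg) over time realizing the three stages.

    The fast-swim amplitude ramps in over ~3 ms so the body velocity stays
    continuous across the counterbend / fast-swim transition.
    """
    T1, T2, T3 = (d * 1e-3 for d in params.stage_durations)
    theta = np.zeros_like(t)
    s1 = t < T1
    theta[s1] = params.cbend_amplitude * np.sin(np.pi * t[s1] / T1) ** 2
    s2 = (t >= T1) & (t < T1 + T2)
    theta[s2] = -params.counterbend_amplitude * np.sin(
        np.pi * (t[s2] - T1) / T2) ** 2
    s3 = t >= T1 + T2
    tau = t[s3] - T1 - T2
    theta[s3] = (params.fastswim_amplitude * _smoothstep(tau / _FAST_RAMP_S)
                 * np.sin(2.0 * np.pi * params.beat_frequency * tau))
    return theta


def _tangent_angles(params: CStartParams, profile_length: float,
                    t: float, s: np.ndarray) -> np.ndarray:
    """Tangent angle phi(s, t) [rad] along the body at time t.

    Bend stages distribute the head-tail angle with a posteriorly growing
    envelope W(s) (W(0)=0, W(L)=1); the fast-swim stage uses a traveling wave
    A * B(s) * sin(w tau - 2 pi s / L) whose boundary values keep the
    head-tail angle exactly A * sin(w tau).
    """
    L = profile_length
    x = s / L
    T1, T2, _ = (d * 1e-3 for d in params.stage_durations)
    if t < T1 + T2:
        theta = _headtail_angle_trace(params, np.array([t]))[0]
        W = x ** 1.5
        return np.deg2rad(theta) * W
    tau = t - T1 - T2
    A = np.deg2rad(params.fastswim_amplitude) * _smoothstep(tau / _FAST_RAMP_S)
    omega = 2.0 * np.pi * params.beat_frequency
    B = x ** 1.5
    return A * B * np.sin(omega * tau - 2.0 * np.pi * x)


def _integrate_midline(phi: np.ndarray, L: float) -> np.ndarray:
    """Integrate tangent angles into a midline of 301 points (mm)."""
    n_seg = phi.size - 1
    ds = L / n_seg
    # midpoint tangents for second-order accuracy
    mid = 0.5 * (phi[:-1] + phi[1:])
    steps = np.stack([np.cos(mid), np.sin(mid)], axis=1) * ds
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts


def _silhouette_moments(points: np.ndarray, widths: np.ndarray,
                        L: float) -> tuple[np.ndarray, np.ndarray]:
    """Width-weighted centroid and second-moment tensor of the swept body.

    Approximates the silhouette as transverse strips of half-width w: each
    strip contributes mass 2 w ds at the midline point plus an in-plane
    spread w^2/3 along its normal.
    """
    n_seg = points.shape[0] - 1
    ds = L / n_seg
    m = 2.0 * widths * ds
    M = m.sum()
    c = (m[:, None] * points).sum(axis=0) / M
    r = points - c
    cov = (m[:, None, None] * (r[:, :, None] * r[:, None, :])).sum(axis=0)
    # strip spread along the local normal
    tang = np.gradient(points, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    spread = (m * widths**2 / 3.0)
    cov += (spread[:, None, None] * (nrm[:, :, None] * nrm[:, None, :])).sum(axis=0)
    cov /= M
    return c, cov


def _principal_angle(cov: np.ndarray) -> float:
    """Orientation (rad) of the principal axis of a 2x2 second-moment tensor."""
    return 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])


def _rot(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def make_cstart_kinematics(
    params: CStartParams, profile: BodyProfile | None = None
) -> MidlineKinematics:
    """Generate per-frame body-frame midlines plus ground-truth traces.

    Returns midlines normalized to the silhouette-momentum convention (see
    :class:`MidlineKinematics`), the exact head-tail-angle and mean-joint-angle
    traces, and the superposed rigid motion used later by the rasterizer.
    """
    if profile is None:
        profile = default_profile()
    L = profile.standard_length
    n_frames = int(round(params.total_duration_ms * 1e-3 * params.frame_rate)) + 1
    t = np.arange(n_frames) * params.dt
    s = np.linspace(0.0, L, 301)
    widths = profile.half_width(s)

    midlines = np.empty((n_frames, 301, 2))
    ht = np.empty(n_frames)
    mj = np.empty(n_frames)
    prev_angle = None
    for i, ti in enumerate(t):
        phi = _tangent_angles(params, L, float(ti), s)
        pts = _integrate_midline(phi, L)
        c, cov = _silhouette_moments(pts, widths, L)
        ang = _principal_angle(cov)
        if prev_angle is not None:
            # continuous branch of the (pi-periodic) principal axis
            k = np.round((prev_angle - ang) / np.pi)
            ang = ang + k * np.pi
        prev_angle = ang
        pts = (pts - c) @ _rot(-ang).T
        midlines[i] = pts
        turn = np.diff(phi)
        ht[i] = np.rad2deg(phi[-1] - phi[0])
        mj[i] = np.rad2deg(turn.mean())

    v = np.asarray(params.superposed_translation, dtype=float)
    cm = v[None, :] * t[:, None]
    alpha = params.superposed_rotation * t
    return MidlineKinematics(t=t, midlines=midlines, head_tail_angle=ht,
                             mean_joint_angle=mj, cm=cm, alpha=alpha,
                             beat_frequency=params.beat_frequency,
                             params=params)


def swimmer_polygon(midline: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Closed silhouette polygon (mm) of a midline swept by half-widths."""
    tang = np.gradient(midline, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    left = midline + widths[:, None] * nrm
    right = midline - widths[:, None] * nrm
    return np.vstack([left, right[::-1]])


def rasterize_swimmer(
    kin: MidlineKinematics,
    profile: BodyProfile,
    params: CStartParams,
    start_position: tuple[float, float] | None = None,
) -> FrameStack:
    """Render a synthetic silhouette movie: dark fish on a bright background.

    The ground-truth rigid motion of ``kin`` is applied on top of the
    body-frame deformation; the rendered stack carries the generator's own
    binary silhouettes in ``ground_truth_masks``. The fish starts centered in
    the window unless ``start_position`` (mm) is given.
    """
    W, H = params.image_size
    scale = params.pixel_scale
    if start_position is None:
        start_position = ((W - 1) * scale / 2.0, (H - 1) * scale / 2.0)
    p0 = np.asarray(start_position, dtype=float)
    rng = np.random.default_rng(params.seed)

    s = np.linspace(0.0, profile.standard_length, 301)
    widths = profile.half_width(s)
    # finite imaging resolution: the thin caudal margin still covers about a
    # pixel on the sensor, so floor the swept half-width away from the tips
    widths[1:-1] = np.maximum(widths[1:-1], 0.8 * scale)

    from skimage.draw import polygon as draw_polygon

    frames = np.empty((kin.n_frames, H, W), dtype=np.uint8)
    masks = np.zeros((kin.n_frames, H, W), dtype=bool)
    for i in range(kin.n_frames):
        R = _rot(np.deg2rad(kin.alpha[i]))
        world = kin.midlines[i] @ R.T + p0 + kin.cm[i]
        poly = swimmer_polygon(world, widths)
        cols = poly[:, 0] / scale
        rows = (H - 1) - poly[:, 1] / scale
        if (cols.min() < 0 or cols.max() > W - 1
                or rows.min() < 0 or rows.max() > H - 1):
            raise GenerationError(
                f"fish exits the image window at frame {i}")
        rr, cc = draw_polygon(rows, cols, shape=(H, W))
        mask = np.zeros((H, W), dtype=bool)
        mask[rr, cc] = True
        masks[i] = mask
        img = np.full((H, W), 230.0)
        img[mask] = 25.0
        if params.noise_level > 0:
            img += rng.normal(0.0, params.noise_level * 255.0, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    return FrameStack(frames=frames, dt=params.dt, pixel_scale=scale,
                      ground_truth_masks=masks)


def make_slice_stack(
    profile: BodyProfile,
    spacing_um: float = 48.0,
    missing_fraction: float = 0.0,
    px_um: float = 10.0,
    seed: int = 0,
    fin_half_thickness_um: float = 20.0,
) -> SliceStack:
    """Emit a stack of binary transverse cross-sections of the body.

    Each section is a superellipse (exponent 2) of the local half-width and
    half-height, with a thin dorsoventral fin-fold blade over the posterior
    body; every slice is bilaterally symmetric by construction. A seeded
    random subset of the interior slices is removed when
    ``missing_fraction > 0`` (the first and last slices are always kept so
    that interpolation stays bracketed).
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    L_um = profile.standard_length * 1e3
    n = int(np.floor(L_um / spacing_um)) + 1
    positions = np.arange(n) * spacing_um

    wmax_um = profile.half_width_table.max() * 1e3
    hmax_um = (profile.half_height_table.max() + profile.finfold_extent) * 1e3
    half_w_px = int(np.ceil(wmax_um / px_um)) + 2
    half_h_px = int(np.ceil(hmax_um / px_um)) + 2
    # symmetric lateral axis: odd pixel count centered on the midplane
    ys = np.arange(-half_w_px, half_w_px + 1) * px_um  # lateral, um
    zs = np.arange(-half_h_px, half_h_px + 1) * px_um  # dorsoventral, um

    YY, ZZ = np.meshgrid(ys, zs)
    images = np.zeros((n, zs.size, ys.size), dtype=bool)
    for i, pos in enumerate(positions):
        s_mm = pos * 1e-3
        w = profile.half_width(np.array([s_mm]))[0] * 1e3
        h = profile.half_height(np.array([s_mm]))[0] * 1e3
        if w > px_um / 2 and h > px_um / 2:
            images[i] = (YY / w) ** 2 + (ZZ / h) ** 2 <= 1.0
        if s_mm > 0.35 * profile.standard_length:
            ext = profile.finfold_extent * 1e3
            blade = (np.abs(YY) <= fin_half_thickness_um) & \
                    (np.abs(ZZ) <= h + ext)
            images[i] |= blade

    if missing_fraction > 0:
        rng = np.random.default_rng(seed)
        interior = np.arange(1, n - 1)
        n_drop = int(round(missing_fraction * n))
        drop = rng.choice(interior, size=min(n_drop, interior.size),
                          replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        images = images[keep]
        positions = positions[keep]

    return SliceStack(images=images, positions_um=positions, px_um=px_um)
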