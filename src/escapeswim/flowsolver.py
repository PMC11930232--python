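"""Penalized incompressible Navier-Stokes solver on a staggered grid.

The momentum equation is solved in the whole computational domain, fluid and
solid alike, with a Brinkman-type penalty term chi * lambda * (us - u)
driving the fluid velocity toward the solid's velocity field inside the
body's characteristic function chi:

    du/dt + (u . grad) u = -grad p / rho + nu lap u + chi lambda (us - u)
    div u = 0

Discretization: 2D MAC (marker-and-cell) staggered grid; explicit
second-order-centered advection and diffusion, implicit penalization
(unconditionally stable in lambda), and an incremental pressure projection
whose Poisson equation is solved exactly by DCT (no-slip box, Neumann
pressure) or FFT (periodic benchmarks) -- the discrete divergence after
projection is at machine precision.

The body is a deforming polygon carried by Lagrangian markers. Its rigid
translation and rotation are not prescribed: they evolve under the
hydrodynamic force and torque obtained by integrating the stress tensor
T = -p I + mu (grad u + grad u^T) over the surface markers, which makes the
escape swim fully self-propelled. All quantities are SI; 2D loads and power
are per unit span and converted to 3D-equivalent values with a configurable
body span (depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn, fft2, ifft2
from scipy.spatial import cKDTree

from .body3d import PlanarBodyMotion

__all__ = [
    "FluidParams",
    "SolverConfig",
    "Grid",
    "FlowState",
    "SolidState",
    "Loads",
    "SimulationTrace",
    "CFLError",
    "taylor_green_state",
    "make_solid_state",
    "step",
    "hydrodynamic_loads",
    "advance_rigid",
    "simulate_escape",
]


class CFLError(RuntimeError):
    pass


@dataclass
class FluidParams:
    """Fluid density (kg/m^3) and dynamic viscosity (Pa s).

    The solid mass density is approximated by the fluid's (the
    eleutheroembryo is near neutrally buoyant).
    """

    rho: float = 1000.0
    mu: float = 0.83e-3

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class SolverConfig:
    """Grid, penalty and run configuration for escape simulations."""

    nx: int = 128                  # cells per side
    domain: float = 0.012          # m, square side (domain centered on cm0)
    bc: str = "wall"               # 'wall' (no-slip box) or 'periodic'
    lam: float = 1e8               # s^-1, penalty coefficient
    cfl: float = 0.35
    depth: float = 0.622e-3        # m, body span for 2D -> 3D conversion
    save_every: int = 0            # flow snapshots every n substeps (0: none)
    max_substep_dt: float = 5e-5   # s


@dataclass
class Grid:
    nx: int
    ny: int
    dx: float
    x0: float = 0.0
    y0: float = 0.0
    bc: str = "wall"

    @property
    def lx(self) -> float:
        return self.nx * self.dx

    @property
    def ly(self) -> float:
        return self.ny * self.dx

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.dx
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.dx
        return x, y


@dataclass
class FlowState:
    """MAC velocity and pressure: u on x-faces, v on y-faces, p at centers.

    After a penalized step, ``penalty_force`` (N/m span), ``penalty_torque``
    (N, about the body cm) and ``penalty_power`` (W/m span) hold the exact
    momentum, angular momentum and energy the body exchanged with the fluid
    through the penalty term during that step.
    """

    grid: Grid
    u: np.ndarray      # (ny, nx+1)
    v: np.ndarray      # (ny+1, nx)
    p: np.ndarray      # (ny, nx)
    t: float = 0.0
    penalty_force: np.ndarray | None = None
    penalty_torque: float | None = None
    penalty_power: float | None = None

    @classmethod
    def quiescent(cls, grid: Grid) -> "FlowState":
        return cls(grid=grid,
                   u=np.zeros((grid.ny, grid.nx + 1)),
                   v=np.zeros((grid.ny + 1, grid.nx)),
                   p=np.zeros((grid.ny, grid.nx)))

    def centered_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        return uc, vc

    def divergence(self) -> np.ndarray:
        dx = self.grid.dx
        return ((self.u[:, 1:] - self.u[:, :-1])
                + (self.v[1:, :] - self.v[:-1, :])) / dx

    def kinetic_energy(self) -> float:
        """Integral of |u|^2 / 2 per unit span (m^4/s^2 x rho gives J/m)."""
        uc, vc = self.centered_velocity()
        return float(0.5 * np.sum(uc**2 + vc**2) * self.grid.dx**2)


@dataclass
class Loads:
    """Hydrodynamic force (N/m span) and torque (N) on the body, about cm."""

    F: np.ndarray
    M: float


@dataclass
class SolidState:
    """Characteristic function, surface markers, and rigid state of the body.

    ``chi`` is the mollified solid indicator at cell centers; ``us_u/us_v``
    the solid velocity field at the grid faces (zero outside chi's support).
    ``markers`` are the boundary polygon vertices (m, world frame), with
    outward ``normals`` and quadrature weights ``ds``. The rigid state is
    (cm, theta, u_bar, omega); ``area`` and ``J`` (per unit span, about cm)
    are recomputed from the current polygon.
    """

    chi: np.ndarray
    us_u: np.ndarray
    us_v: np.ndarray
    lam: float
    markers: np.ndarray
    normals: np.ndarray
    ds: np.ndarray
    marker_us: np.ndarray
    cm: np.ndarray
    theta: float
    u_bar: np.ndarray
    omega: float
    area: float
    J: float


def polygon_properties(poly: np.ndarray) -> tuple[float, np.ndarray, float]:
    """(area, centroid, second moment about centroid) of a simple polygon."""
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * cross.sum()
    if abs(A) < 1e-300:
        raise ValueError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * A)
    cy = ((y + y1) * cross).sum() / (6.0 * A)
    Ix = ((y**2 + y * y1 + y1**2) * cross).sum() / 12.0
    Iy = ((x**2 + x * x1 + x1**2) * cross).sum() / 12.0
    Izz = Ix + Iy - A * (cx**2 + cy**2)
    if A < 0:
        A, Izz = -A, -Izz
    return float(A), np.array([cx, cy]), float(Izz)


# ---------------------------------------------------------------------------
# Poisson solvers (exact for the MAC 5-point Laplacian)


def _poisson_neumann(rhs: np.ndarray, dx: float) -> np.ndarray:
    ny, nx = rhs.shape
    rhat = dctn(rhs, type=2, norm="ortho")
    kx = (2.0 * np.cos(np.pi * np.arange(nx) / nx) - 2.0) / dx**2
    ky = (2.0 * np.cos(np.pi * np.arange(ny) / ny) - 2.0) / dx**2
    denom = kx[None, :] + ky[:, None]
    denom[0, 0] = 1.0
    phat = rhat / denom
    phat[0, 0] = 0.0
    return idctn(phat, type=2, norm="ortho")


def _poisson_periodic(rhs: np.ndarray, dx: float) -> np.ndarray:
    ny, nx = rhs.shape
    rhat = fft2(rhs)
    kx = (2.0 * np.cos(2.0 * np.pi * np.arange(nx) / nx) - 2.0) / dx**2
    ky = (2.0 * np.cos(2.0 * np.pi * np.arange(ny) / ny) - 2.0) / dx**2
    denom = kx[None, :] + ky[:, None]
    denom[0, 0] = 1.0
    phat = rhat / denom
    phat[0, 0] = 0.0
    return np.real(ifft2(phat))


# ---------------------------------------------------------------------------
# discrete operators


def _ghost_u(u: np.ndarray, bc: str) -> np.ndarray:
    """u with one ghost row above/below and wrap/ghost columns: (ny+2, nx+1
    or nx+3 for periodic x handled separately)."""
    if bc == "periodic":
        # u[:, 0] == u[:, nx] identified
        g = np.empty((u.shape[0] + 2, u.shape[1]))
        g[1:-1] = u
        g[0] = u[-1]
        g[-1] = u[0]
        return g
    g = np.empty((u.shape[0] + 2, u.shape[1]))
    g[1:-1] = u
    g[0] = -u[0]       # no-slip: tangential velocity reflects odd
    g[-1] = -u[-1]
    return g


def _ghost_v(v: np.ndarray, bc: str) -> np.ndarray:
    if bc == "periodic":
        g = np.empty((v.shape[0], v.shape[1] + 2))
        g[:, 1:-1] = v
        g[:, 0] = v[:, -1]
        g[:, -1] = v[:, 0]
        return g
    g = np.empty((v.shape[0], v.shape[1] + 2))
    g[:, 1:-1] = v
    g[:, 0] = -v[:, 0]
    g[:, -1] = -v[:, -1]
    return g


def _rhs_u(u: np.ndarray, v: np.ndarray, grid: Grid, nu: float) -> np.ndarray:
    """Advection + diffusion tendency for u at x-faces."""
    dx = grid.dx
    bc = grid.bc
    ug = _ghost_u(u, bc)                       # (ny+2, nx+1)
    vg = _ghost_v(v, bc)                       # (ny+1, nx+2)

    # d(uu)/dx at faces, from cell-centered uu
    uc = 0.5 * (u[:, :-1] + u[:, 1:])          # (ny, nx)
    if bc == "periodic":
        ucx = np.concatenate([uc[:, -1:], uc, uc[:, :1]], axis=1)
        duu = (ucx[:, 1:] ** 2 - ucx[:, :-1] ** 2) / dx   # (ny, nx+1)
    else:
        duu = np.zeros_like(u)
        duu[:, 1:-1] = (uc[:, 1:] ** 2 - uc[:, :-1] ** 2) / dx

    # d(uv)/dy at faces, from corner fluxes
    u_cor = 0.5 * (ug[:-1, :] + ug[1:, :])     # (ny+1, nx+1)
    v_cor = 0.5 * (vg[:, :-1] + vg[:, 1:])     # (ny+1, nx+1)
    flux = u_cor * v_cor
    duv = (flux[1:, :] - flux[:-1, :]) / dx    # (ny, nx+1)

    # Laplacian
    lap = np.zeros_like(u)
    lap += (ug[:-2, :] - 2.0 * ug[1:-1, :] + ug[2:, :]) / dx**2
    if bc == "periodic":
        ux = np.concatenate([u[:, -2:-1], u, u[:, 1:2]], axis=1)
        lap += (ux[:, :-2] - 2.0 * ux[:, 1:-1] + ux[:, 2:]) / dx**2
    else:
        lap[:, 1:-1] += (u[:, :-2] - 2.0 * u[:, 1:-1] + u[:, 2:]) / dx**2

    out = -(duu + duv) + nu * lap
    if bc != "periodic":
        out[:, 0] = 0.0
        out[:, -1] = 0.0
    return out


def _rhs_v(u: np.ndarray, v: np.ndarray, grid: Grid, nu: float) -> np.ndarray:
    dx = grid.dx
    bc = grid.bc
    ug = _ghost_u(u, bc)
    vg = _ghost_v(v, bc)

    vc = 0.5 * (v[:-1, :] + v[1:, :])          # (ny, nx)
    if bc == "periodic":
        vcy = np.concatenate([vc[-1:, :], vc, vc[:1, :]], axis=0)
        dvv = (vcy[1:, :] ** 2 - vcy[:-1, :] ** 2) / dx
    else:
        dvv = np.zeros_like(v)
        dvv[1:-1, :] = (vc[1:, :] ** 2 - vc[:-1, :] ** 2) / dx

    u_cor = 0.5 * (ug[:-1, :] + ug[1:, :])
    v_cor = 0.5 * (vg[:, :-1] + vg[:, 1:])
    flux = u_cor * v_cor
    duv = (flux[:, 1:] - flux[:, :-1]) / dx    # (ny+1, nx)

    lap = np.zeros_like(v)
    lap += (vg[:, :-2] - 2.0 * vg[:, 1:-1] + vg[:, 2:]) / dx**2
    if bc == "periodic":
        vy = np.concatenate([v[-2:-1, :], v, v[1:2, :]], axis=0)
        lap += (vy[:-2, :] - 2.0 * vy[1:-1, :] + vy[2:, :]) / dx**2
    else:
        lap[1:-1, :] += (v[:-2, :] - 2.0 * v[1:-1, :] + v[2:, :]) / dx**2

    out = -(dvv + duv) + nu * lap
    if bc != "periodic":
        out[0, :] = 0.0
        out[-1, :] = 0.0
    return out


def _project(u: np.ndarray, v: np.ndarray, p: np.ndarray, grid: Grid,
             rho: float, dt: float) -> tuple[np.ndarray, np.ndarray,
                                             np.ndarray]:
    dx = grid.dx
    div = ((u[:, 1:] - u[:, :-1]) + (v[1:, :] - v[:-1, :])) / dx
    rhs = rho / dt * div
    if grid.bc == "periodic":
        phi = _poisson_periodic(rhs, dx)
        dpx = (np.roll(phi, -1, axis=1) - phi) / dx
        u = u.copy()
        u[:, :-1] -= dt / rho * np.roll(dpx, 1, axis=1)
        u[:, -1] = u[:, 0]
        dpy = (np.roll(phi, -1, axis=0) - phi) / dx
        v = v.copy()
        v[:-1, :] -= dt / rho * np.roll(dpy, 1, axis=0)
        v[-1, :] = v[0, :]
    else:
        phi = _poisson_neumann(rhs, dx)
        u = u.copy()
        v = v.copy()
        u[:, 1:-1] -= dt / rho * (phi[:, 1:] - phi[:, :-1]) / dx
        v[1:-1, :] -= dt / rho * (phi[1:, :] - phi[:-1, :]) / dx
    return u, v, p + phi


def step(flow: FlowState, solid: SolidState | None, params: FluidParams,
         dt: float) -> FlowState:
    """Advance the penalized Navier-Stokes system by one time step.

    Explicit advection-diffusion, implicit penalization
    u = (u* + lam dt chi us) / (1 + lam dt chi), incremental pressure
    projection. Raises :class:`CFLError` (proposing a maximum dt) when the
    advective or diffusive stability limit is violated.
    """
    grid = flow.grid
    dx = grid.dx
    umax = max(float(np.abs(flow.u).max()), float(np.abs(flow.v).max()))
    if solid is not None:
        umax = max(umax, float(np.abs(solid.us_u).max()),
                   float(np.abs(solid.us_v).max()))
    if umax > 0 and dt > dx / umax:
        raise CFLError(f"advective CFL violated: use dt <= {dx / umax:.3e} s")
    dt_diff = 0.25 * dx**2 / params.nu
    if dt > dt_diff:
        raise CFLError(f"diffusive limit violated: use dt <= {dt_diff:.3e} s")

    u = flow.u + dt * _rhs_u(flow.u, flow.v, grid, params.nu)
    v = flow.v + dt * _rhs_v(flow.u, flow.v, grid, params.nu)

    pen_F = pen_M = pen_P = None
    if solid is not None and solid.lam > 0:
        chi = solid.chi
        chi_u = np.zeros_like(u)
        chi_u[:, 1:-1] = 0.5 * (chi[:, :-1] + chi[:, 1:])
        chi_v = np.zeros_like(v)
        chi_v[1:-1, :] = 0.5 * (chi[:-1, :] + chi[1:, :])
        if grid.bc == "periodic":
            chi_u[:, 0] = chi_u[:, -1] = 0.5 * (chi[:, 0] + chi[:, -1])
            chi_v[0, :] = chi_v[-1, :] = 0.5 * (chi[0, :] + chi[-1, :])
        lu = solid.lam * dt * chi_u
        lv = solid.lam * dt * chi_v
        u_star, v_star = u, v
        u = (u_star + lu * solid.us_u) / (1.0 + lu)
        v = (v_star + lv * solid.us_v) / (1.0 + lv)
        # exact momentum / energy exchanged through the penalty term:
        # f dt = (u_new - u*) per face, times rho dV
        dA = dx * dx
        fu = params.rho * (u - u_star) / dt * dA
        fv = params.rho * (v - v_star) / dt * dA
        fluid_fx = float(fu.sum())
        fluid_fy = float(fv.sum())
        pen_F = -np.array([fluid_fx, fluid_fy])
        xu = grid.x0 + np.arange(grid.nx + 1) * dx
        yu = grid.y0 + (np.arange(grid.ny) + 0.5) * dx
        xv = grid.x0 + (np.arange(grid.nx) + 0.5) * dx
        yv = grid.y0 + np.arange(grid.ny + 1) * dx
        rxu = xu[None, :] - solid.cm[0]
        ryu = yu[:, None] - solid.cm[1]
        rxv = xv[None, :] - solid.cm[0]
        ryv = yv[:, None] - solid.cm[1]
        # torque on fluid = sum r x f; on body = negative
        pen_M = -float((rxv * fv).sum() - (ryu * fu).sum())
        # power the body expends: - integral f . us  (f = force on fluid)
        pen_P = float((fu * solid.us_u).sum() + (fv * solid.us_v).sum())

    if grid.bc != "periodic":
        u[:, 0] = 0.0
        u[:, -1] = 0.0
        v[0, :] = 0.0
        v[-1, :] = 0.0

    u, v, p = _project(u, v, flow.p, grid, params.rho, dt)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise FloatingPointError("solver diverged: non-finite velocity field")
    return FlowState(grid=grid, u=u, v=v, p=p, t=flow.t + dt,
                     penalty_force=pen_F, penalty_torque=pen_M,
                     penalty_power=pen_P)


def taylor_green_state(grid: Grid, amplitude: float = 1.0) -> FlowState:
    """Analytic Taylor-Green vortex sampled on the MAC grid (periodic box).

    u = A cos(kx) sin(ky), v = -A sin(kx) cos(ky) with k = 2 pi / L; the
    exact solution decays as exp(-2 nu k^2 t).
    """
    k = 2.0 * np.pi / grid.lx
    xf = grid.x0 + np.arange(grid.nx + 1) * grid.dx
    yc = grid.y0 + (np.arange(grid.ny) + 0.5) * grid.dx
    u = amplitude * np.cos(k * xf)[None, :] * np.sin(k * yc)[:, None]
    xc = grid.x0 + (np.arange(grid.nx) + 0.5) * grid.dx
    yf = grid.y0 + np.arange(grid.ny + 1) * grid.dx
    v = -amplitude * np.sin(k * xc)[None, :] * np.cos(k * yf)[:, None]
    p = np.zeros((grid.ny, grid.nx))
    return FlowState(grid=grid, u=u, v=v, p=p)


# ---------------------------------------------------------------------------
# solid state assembly and loads


def _bilinear(field: np.ndarray, x: np.ndarray, y: np.ndarray,
              grid: Grid) -> np.ndarray:
    """Bilinear sample of a cell-centered field at world points (clamped)."""
    fx = (x - grid.x0) / grid.dx - 0.5
    fy = (y - grid.y0) / grid.dx - 0.5
    i0 = np.clip(np.floor(fx).astype(int), 0, grid.nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, grid.ny - 2)
    tx = np.clip(fx - i0, 0.0, 1.0)
    ty = np.clip(fy - j0, 0.0, 1.0)
    f00 = field[j0, i0]
    f01 = field[j0, i0 + 1]
    f10 = field[j0 + 1, i0]
    f11 = field[j0 + 1, i0 + 1]
    return ((1 - ty) * ((1 - tx) * f00 + tx * f01)
            + ty * ((1 - tx) * f10 + tx * f11))


def make_solid_state(
    boundary: np.ndarray,
    interior_pts: np.ndarray,
    interior_vel: np.ndarray,
    grid: Grid,
    lam: float,
    cm: np.ndarray,
    theta: float,
    u_bar: np.ndarray,
    omega: float,
    rho: float = 1000.0,
) -> SolidState:
    """Assemble chi, the solid velocity field, and surface quadrature.

    ``boundary`` is the world-frame body polygon (m); ``interior_pts`` /
    ``interior_vel`` a world-frame marker cloud carrying the full solid
    velocity us = u_bar + omega ^ r + u_tilde. chi is a smoothed Heaviside
    of the signed distance, mollified over one grid cell; us is extended to
    the grid by nearest-marker lookup inside chi's support.
    """
    ny, nx, dx = grid.ny, grid.nx, grid.dx
    x, y = grid.cell_centers()

    lo = boundary.min(axis=0) - 4 * dx
    hi = boundary.max(axis=0) + 4 * dx
    i0 = max(int((lo[0] - grid.x0) / dx), 0)
    i1 = min(int((hi[0] - grid.x0) / dx) + 1, nx)
    j0 = max(int((lo[1] - grid.y0) / dx), 0)
    j1 = min(int((hi[1] - grid.y0) / dx) + 1, ny)
    if i0 >= i1 or j0 >= j1:
        raise ValueError("body outside the computational domain")

    from matplotlib.path import Path
    XX, YY = np.meshgrid(x[i0:i1], y[j0:j1])
    pts = np.stack([XX.ravel(), YY.ravel()], axis=1)
    inside = Path(boundary).contains_points(pts).reshape(XX.shape)
    sdf = (ndimage.distance_transform_edt(~inside)
           - ndimage.distance_transform_edt(inside)) * dx
    chi_loc = np.clip(0.5 - sdf / dx, 0.0, 1.0)
    chi = np.zeros((ny, nx))
    chi[j0:j1, i0:i1] = chi_loc

    # solid velocity at faces by nearest interior marker
    tree = cKDTree(interior_pts)
    us_u = np.zeros((ny, nx + 1))
    us_v = np.zeros((ny + 1, nx))
    chi_u = np.zeros_like(us_u)
    chi_u[:, 1:-1] = 0.5 * (chi[:, :-1] + chi[:, 1:])
    chi_v = np.zeros_like(us_v)
    chi_v[1:-1, :] = 0.5 * (chi[:-1, :] + chi[1:, :])
    ju, iu = np.nonzero(chi_u > 0)
    if ju.size:
        px = grid.x0 + iu * dx
        py = grid.y0 + (ju + 0.5) * dx
        _, idx = tree.query(np.stack([px, py], axis=1))
        us_u[ju, iu] = interior_vel[idx, 0]
    jv, iv = np.nonzero(chi_v > 0)
    if jv.size:
        px = grid.x0 + (iv + 0.5) * dx
        py = grid.y0 + jv * dx
        _, idx = tree.query(np.stack([px, py], axis=1))
        us_v[jv, iv] = interior_vel[idx, 1]

    # boundary quadrature: outward normals of the CCW polygon
    poly = boundary
    area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                   - np.roll(poly[:, 0], -1) * poly[:, 1])
    if area2 < 0:
        poly = poly[::-1]
    seg = np.roll(poly, -1, axis=0) - poly
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 1e-12
    mid = 0.5 * (poly + np.roll(poly, -1, axis=0))[keep]
    tang = seg[keep] / seg_len[keep][:, None]
    normals = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    ds = seg_len[keep]
    _, idx = tree.query(mid)
    marker_us = interior_vel[idx]

    A2, cpoly, Izz_c = polygon_properties(poly)
    d2 = float(((cpoly - cm) ** 2).sum())
    J = rho * (Izz_c + A2 * d2)  # parallel-axis shift to the rigid cm

    return SolidState(chi=chi, us_u=us_u, us_v=us_v, lam=lam,
                      markers=mid, normals=normals, ds=ds,
                      marker_us=marker_us, cm=np.asarray(cm, dtype=float),
                      theta=float(theta), u_bar=np.asarray(u_bar, dtype=float),
                      omega=float(omega), area=A2, J=J)


def surface_tractions(flow: FlowState, solid: SolidState,
                      params: FluidParams,
                      normal_offset_cells: float = 1.5) -> np.ndarray:
    """Stress-tensor tractions T.n at the surface markers (N/m^2).

    T = -p I + mu (grad u + grad u^T). The pressure is interpolated from the
    cell centers at a point ``normal_offset_cells`` grid cells outward along
    the surface normal (inside the one-cell mollified interface of the
    penalized body the fields are not physical). The viscous part uses a
    one-sided wall gradient: the velocity sampled at the offset point
    differenced against the known surface velocity us at the marker, which
    resolves the boundary-layer shear that a centered interior gradient
    smears away at these grid sizes.
    """
    grid = flow.grid
    uc, vc = flow.centered_velocity()
    dx = grid.dx
    off = normal_offset_cells * dx
    n = solid.normals
    mx = solid.markers[:, 0] + off * n[:, 0]
    my = solid.markers[:, 1] + off * n[:, 1]
    if (mx.min() < grid.x0 or mx.max() > grid.x0 + grid.lx
            or my.min() < grid.y0 or my.max() > grid.y0 + grid.ly):
        raise ValueError("surface markers outside the grid")
    p_m = _bilinear(flow.p, mx, my, grid)
    u1 = np.stack([_bilinear(uc, mx, my, grid),
                   _bilinear(vc, mx, my, grid)], axis=1)
    du = (u1 - solid.marker_us) / off        # du/dn, vector
    tvec = np.stack([-n[:, 1], n[:, 0]], axis=1)
    dut = (du * tvec).sum(axis=1)            # tangential shear rate
    dun = (du * n).sum(axis=1)               # normal strain rate
    trac_visc = (params.mu * dut)[:, None] * tvec \
        + (2.0 * params.mu * dun)[:, None] * n
    trac_press = (-p_m)[:, None] * n
    return trac_press + trac_visc


def hydrodynamic_loads(flow: FlowState, solid: SolidState,
                       params: FluidParams) -> Loads:
    """Net hydrodynamic force (N/m span) and torque (N) about the cm."""
    trac = surface_tractions(flow, solid, params)
    F = (trac * solid.ds[:, None]).sum(axis=0)
    r = solid.markers - solid.cm
    M = float(((r[:, 0] * trac[:, 1] - r[:, 1] * trac[:, 0])
               * solid.ds).sum())
    return Loads(F=F, M=M)


def instantaneous_power_2d(flow: FlowState, solid: SolidState,
                           params: FluidParams) -> float:
    """Mechanical power the body exerts on the fluid, per unit span (W/m).

    P = -surface integral of (T.n).us: positive when the body works against
    the fluid tractions.
    """
    trac = surface_tractions(flow, solid, params)
    return float(-np.sum((trac * solid.marker_us).sum(axis=1) * solid.ds))


def advance_rigid(solid: SolidState, loads: Loads, params: FluidParams,
                  dt: float) -> SolidState:
    """Advance the rigid translation/rotation ODEs by one explicit step.

    rho_s A du_bar/dt = F and d(J omega)/dt = M per unit span, with J
    recomputed from the current shape by the caller; cm and theta advance
    with the updated velocities.
    """
    if solid.J <= 0:
        raise ValueError("singular inertia")
    m = params.rho * solid.area
    u_bar = solid.u_bar + loads.F * dt / m
    omega = (solid.J * solid.omega + loads.M * dt) / solid.J
    cm = solid.cm + u_bar * dt
    theta = solid.theta + omega * dt
    return replace(solid, u_bar=u_bar, omega=omega, cm=cm, theta=theta)


# ---------------------------------------------------------------------------
# full escape simulation


@dataclass
class SimulationTrace:
    """Time series of the coupled escape run (SI units; power in W)."""

    t: np.ndarray
    cm: np.ndarray                 # (n, 2) m
    theta: np.ndarray              # (n,) rad
    u_bar: np.ndarray              # (n, 2) m/s
    omega: np.ndarray              # (n,) rad/s
    F: np.ndarray                  # (n, 2) N/m span
    M: np.ndarray                  # (n,) N
    P: np.ndarray                  # (n,) W (span-converted)
    head_tail_angle: np.ndarray    # (n,) deg, interpolated body trace
    depth: float
    snapshots: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)

    def distance_traveled(self) -> float:
        """Cumulative center-of-mass path length (m)."""
        return float(np.sum(np.hypot(*np.diff(self.cm, axis=0).T)))


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def simulate_escape(
    motion: PlanarBodyMotion,
    params: FluidParams,
    cfg: SolverConfig | None = None,
    n_boundary: int = 160,
) -> SimulationTrace:
    """Run the fully coupled escape-swim simulation from rest.

    The body-frame deformation (positions and u-tilde) is linearly
    interpolated in time to the solver step; the rigid translation and
    rotation are recomputed by the solver from the hydrodynamic loads. The
    fish and the fluid start at rest, with the domain centered on the
    initial center of mass. The acquisition interval is subdivided into
    solver substeps satisfying the CFL condition.
    """
    if cfg is None:
        cfg = SolverConfig()
    grid = Grid(nx=cfg.nx, ny=cfg.nx, dx=cfg.domain / cfg.nx,
                x0=-cfg.domain / 2.0, y0=-cfg.domain / 2.0, bc=cfg.bc)
    flow = FlowState.quiescent(grid)

    # body-frame data in meters; boundary decimated for quadrature speed
    bnd = motion.boundary * 1e-3
    bnd_v = motion.boundary_vel * 1e-3
    if bnd.shape[1] > n_boundary:
        sel = np.linspace(0, bnd.shape[1] - 1, n_boundary).astype(int)
        bnd, bnd_v = bnd[:, sel], bnd_v[:, sel]
    intr = motion.interior.reshape(motion.n_frames, -1, 2) * 1e-3
    intr_v = motion.interior_vel.reshape(motion.n_frames, -1, 2) * 1e-3
    t_frames = motion.t
    dt_m = motion.dt

    cm = np.zeros(2)
    theta = 0.0
    u_bar = np.zeros(2)
    omega = 0.0

    rec: dict[str, list] = {k: [] for k in
                            ("t", "cm", "theta", "u_bar", "omega",
                             "F", "M", "P", "ht")}
    snapshots: list[FlowState] = []
    snap_t: list[float] = []
    margin = 2.5 * grid.dx
    t = 0.0
    istep = 0
    for k in range(motion.n_frames - 1):
        # substep count from the current velocity scale
        body_v = max(float(np.abs(intr_v[k]).max()),
                     float(np.abs(intr_v[k + 1]).max()))
        umax = max(float(np.abs(flow.u).max()), float(np.abs(flow.v).max()),
                   1.2 * (body_v + float(np.linalg.norm(u_bar))),
                   1e-3)
        dt_cfl = cfg.cfl * grid.dx / umax
        dt_diff = 0.2 * grid.dx**2 / params.nu
        n_sub = max(1, int(np.ceil(
            dt_m / min(dt_cfl, dt_diff, cfg.max_substep_dt))))
        dt = dt_m / n_sub
        for s in range(n_sub):
            tau = (s + 0.5) / n_sub
            Xb = (1 - tau) * intr[k] + tau * intr[k + 1]
            Vb = (1 - tau) * intr_v[k] + tau * intr_v[k + 1]
            Bb = (1 - tau) * bnd[k] + tau * bnd[k + 1]
            Bvb = (1 - tau) * bnd_v[k] + tau * bnd_v[k + 1]
            R = _rot(theta)
            Xw = Xb @ R.T + cm
            Bw = Bb @ R.T + cm
            if (np.abs(Bw - np.array([0.0, 0.0])).max()
                    > cfg.domain / 2.0 - margin):
                raise RuntimeError(
                    f"body reached the domain boundary at t = {t:.4e} s")
            rw = Xw - cm
            Vw = (Vb @ R.T + u_bar
                  + omega * np.stack([-rw[:, 1], rw[:, 0]], axis=1))
            solid = make_solid_state(Bw, Xw, Vw, grid, cfg.lam, cm, theta,
                                     u_bar, omega, rho=params.rho)
            flow = step(flow, solid, params, dt)
            loads = hydrodynamic_loads(flow, solid, params)
            P2d = instantaneous_power_2d(flow, solid, params)
            solid = advance_rigid(solid, loads, params, dt)
            cm, theta = solid.cm, solid.theta
            u_bar, omega = solid.u_bar, solid.omega
            t += dt
            istep += 1
            ht = np.interp(t, t_frames, motion.head_tail_angle)
            rec["t"].append(t)
            rec["cm"].append(cm.copy())
            rec["theta"].append(theta)
            rec["u_bar"].append(u_bar.copy())
            rec["omega"].append(omega)
            rec["F"].append(loads.F.copy())
            rec["M"].append(loads.M)
            rec["P"].append(P2d * cfg.depth)
            rec["ht"].append(ht)
            if cfg.save_every and istep % cfg.save_every == 0:
                snapshots.append(FlowState(grid=grid, u=flow.u.copy(),
                                           v=flow.v.copy(), p=flow.p.copy(),
                                           t=flow.t))
                snap_t.append(t)

    return SimulationTrace(
        t=np.array(rec["t"]), cm=np.array(rec["cm"]),
        theta=np.array(rec["theta"]), u_bar=np.array(rec["u_bar"]),
        omega=np.array(rec["omega"]), F=np.array(rec["F"]),
        M=np.array(rec["M"]), P=np.array(rec["P"]),
        head_tail_angle=np.array(rec["ht"]), depth=cfg.depth,
        snapshots=snapshots, snapshot_times=snap_t)
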