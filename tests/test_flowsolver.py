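"""Solver physics: exact benchmarks, penalization, loads, rigid coupling."""

import numpy as np
import pytest

from escapeswim.flowsolver import (CFLError, FlowState, FluidParams, Grid,
                                   Loads, SolidState, advance_rigid,
                                   hydrodynamic_loads, make_solid_state,
                                   polygon_properties, simulate_escape, step,
                                   surface_tractions, taylor_green_state)


@pytest.fixture
def periodic_grid():
    return Grid(nx=64, ny=64, dx=2 * np.pi / 64, bc="periodic")


class TestStep:
    def test_quiescent_fluid_stays_quiescent(self, periodic_grid):
        fp = FluidParams(rho=1.0, mu=0.01)
        fs = FlowState.quiescent(periodic_grid)
        fs = step(fs, None, fp, 0.01)
        assert np.abs(fs.u).max() == 0.0
        assert np.abs(fs.v).max() == 0.0

    def test_taylor_green_decay_rate(self, periodic_grid):
        fp = FluidParams(rho=1.0, mu=0.02)
        fs = taylor_green_state(periodic_grid)
        dt = 0.005
        for _ in range(400):
            fs = step(fs, None, fp, dt)
        exact = np.exp(-2.0 * fp.nu * fs.t)
        assert np.abs(fs.u).max() == pytest.approx(exact, rel=0.01)

    def test_divergence_machine_precision(self, periodic_grid):
        fp = FluidParams(rho=1.0, mu=0.01)
        fs = taylor_green_state(periodic_grid)
        fs = step(fs, None, fp, 0.005)
        scale = np.abs(fs.u).max() / periodic_grid.dx
        assert np.abs(fs.divergence()).max() < 1e-10 * scale

    def test_cfl_violation_raises_with_proposal(self, periodic_grid):
        fp = FluidParams(rho=1.0, mu=0.001)
        fs = taylor_green_state(periodic_grid)
        with pytest.raises(CFLError, match="dt <="):
            step(fs, None, fp, 1.0)

    def test_diffusive_limit_raises(self, periodic_grid):
        fp = FluidParams(rho=1.0, mu=50.0)
        fs = FlowState.quiescent(periodic_grid)
        with pytest.raises(CFLError, match="diffusive"):
            step(fs, None, fp, 0.1)


def _disc_solid(grid, r0, us=(0.0, 0.0), lam=1e8):
    th = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    bnd = np.stack([r0 * np.cos(th), r0 * np.sin(th)], 1)
    gx, gy = np.meshgrid(np.linspace(-r0, r0, 13), np.linspace(-r0, r0, 13))
    pts = np.stack([gx.ravel(), gy.ravel()], 1)
    pts = pts[(pts**2).sum(1) <= r0**2]
    vel = np.tile(np.asarray(us, dtype=float), (pts.shape[0], 1))
    return make_solid_state(bnd, pts, vel, grid, lam, np.zeros(2), 0.0,
                            np.asarray(us, dtype=float), 0.0)


class TestPenalization:
    def test_interior_velocity_decreases_with_lambda(self):
        fp = FluidParams(rho=1000.0, mu=1e-3)
        maxima = []
        for lam in (1e4, 1e6, 1e8):
            grid = Grid(nx=64, ny=64, dx=0.01 / 64, x0=-0.005, y0=-0.005,
                        bc="periodic")
            fs = FlowState.quiescent(grid)
            fs.u += 0.05
            solid = _disc_solid(grid, 0.0015, lam=lam)
            for _ in range(40):
                fs = step(fs, solid, fp, 2e-5)
            chi_u = np.zeros_like(fs.u)
            chi_u[:, 1:-1] = 0.5 * (solid.chi[:, :-1] + solid.chi[:, 1:])
            maxima.append(np.abs(fs.u[chi_u > 0.99]).max())
        assert maxima[0] > maxima[1] > maxima[2]

    def test_penalty_force_opposes_stream(self):
        grid = Grid(nx=64, ny=64, dx=0.01 / 64, x0=-0.005, y0=-0.005,
                    bc="periodic")
        fp = FluidParams(rho=1000.0, mu=1e-3)
        fs = FlowState.quiescent(grid)
        fs.u += 0.05
        solid = _disc_solid(grid, 0.0015)
        fs = step(fs, solid, fp, 2e-5)
        assert fs.penalty_force[0] > 0.0  # drag pushes the body downstream


class TestLoads:
    def test_constant_pressure_closed_surface_zero_force(self):
        grid = Grid(nx=64, ny=64, dx=1.0 / 64, bc="wall")
        fp = FluidParams(rho=1000.0, mu=1.0)
        fs = FlowState.quiescent(grid)
        fs.p += 42.0
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        bnd = np.stack([0.5 + 0.2 * np.cos(th), 0.5 + 0.2 * np.sin(th)], 1)
        pts = bnd * 0.99
        solid = make_solid_state(bnd, pts, np.zeros_like(pts), grid, 1e8,
                                 np.array([0.5, 0.5]), 0.0, np.zeros(2), 0.0)
        loads = hydrodynamic_loads(fs, solid, fp)
        p_scale = 42.0 * 2 * np.pi * 0.2
        assert np.linalg.norm(loads.F) < 1e-6 * p_scale
        assert abs(loads.M) < 1e-6 * p_scale

    def test_couette_shear_force_on_plate(self):
        """Half-space Couette flow u = gamma (y - y0) above a wall at rest:
        tangential traction mu gamma, force mu gamma A."""
        grid = Grid(nx=64, ny=64, dx=1.0 / 64, bc="wall")
        fp = FluidParams(rho=1000.0, mu=2.0)
        fs = FlowState.quiescent(grid)
        gamma, y0 = 3.0, 0.5
        yc = (np.arange(64) + 0.5) * grid.dx
        fs.u[:] = gamma * np.clip(yc - y0, 0.0, None)[:, None]
        xs = np.linspace(0.3, 0.7, 41)
        mid = np.stack([0.5 * (xs[:-1] + xs[1:]), np.full(40, y0)], 1)
        solid = SolidState(
            chi=np.zeros((64, 64)), us_u=np.zeros((64, 65)),
            us_v=np.zeros((65, 64)), lam=0.0, markers=mid,
            normals=np.tile([0.0, 1.0], (40, 1)),
            ds=np.full(40, xs[1] - xs[0]), marker_us=np.zeros((40, 2)),
            cm=np.array([0.5, y0]), theta=0.0, u_bar=np.zeros(2),
            omega=0.0, area=1.0, J=1.0)
        tr = surface_tractions(fs, solid, fp)
        Fx = (tr[:, 0] * solid.ds).sum()
        assert Fx == pytest.approx(fp.mu * gamma * 0.4, rel=0.02)

    def test_mirror_symmetric_flow_zero_torque(self):
        grid = Grid(nx=64, ny=64, dx=1.0 / 64, bc="wall")
        fp = FluidParams(rho=1000.0, mu=1.0)
        fs = FlowState.quiescent(grid)
        xc = (np.arange(65)) * grid.dx
        fs.u[:] = (xc - 0.5)[None, :]  # symmetric about x=0.5
        th = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        bnd = np.stack([0.5 + 0.15 * np.cos(th), 0.5 + 0.15 * np.sin(th)], 1)
        solid = make_solid_state(bnd, bnd * 0.98 + 0.01,
                                 np.zeros_like(bnd), grid, 1e8,
                                 np.array([0.5, 0.5]), 0.0, np.zeros(2), 0.0)
        loads = hydrodynamic_loads(fs, solid, fp)
        scale = fp.mu * 1.0 * 2 * np.pi * 0.15 * 0.15
        assert abs(loads.M) < 0.05 * scale + 1e-12


class TestAdvanceRigid:
    def _solid(self):
        grid = Grid(nx=32, ny=32, dx=0.01 / 32, x0=-0.005, y0=-0.005,
                    bc="wall")
        return _disc_solid(grid, 0.0012)

    def test_zero_loads_keep_velocities(self):
        s = self._solid()
        out = advance_rigid(s, Loads(F=np.zeros(2), M=0.0),
                            FluidParams(), 1e-4)
        assert np.array_equal(out.u_bar, s.u_bar)
        assert out.omega == s.omega

    def test_constant_force_exact_velocity_increment(self):
        s = self._solid()
        fp = FluidParams()
        F = np.array([2e-3, 0.0])
        dt = 1e-4
        out = s
        for _ in range(10):
            out = advance_rigid(out, Loads(F=F, M=0.0), fp, dt)
        expected = 10 * F[0] * dt / (fp.rho * s.area)
        assert out.u_bar[0] == pytest.approx(expected, rel=1e-12)

    def test_sinusoidal_force_matches_ode(self):
        s = self._solid()
        fp = FluidParams()
        m = fp.rho * s.area
        om = 2 * np.pi * 50.0

        def run(dt, T=0.02):
            out = s
            n = int(round(T / dt))
            for i in range(n):
                F = np.array([1e-3 * np.sin(om * (i + 0.5) * dt), 0.0])
                out = advance_rigid(out, Loads(F=F, M=0.0), fp, dt)
            return out.u_bar[0]

        exact = 1e-3 / (m * om) * (1 - np.cos(om * 0.02))
        v1 = run(2e-5)
        assert v1 == pytest.approx(exact, rel=0.005)


class TestPolygonProperties:
    def test_unit_square(self):
        poly = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        A, c, Izz = polygon_properties(poly)
        assert A == pytest.approx(1.0)
        assert np.allclose(c, [0.5, 0.5])
        assert Izz == pytest.approx(1.0 / 6.0)

    def test_orientation_independent(self):
        poly = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float)
        A1, c1, I1 = polygon_properties(poly)
        A2, c2, I2 = polygon_properties(poly[::-1])
        assert A1 == pytest.approx(A2)
        assert I1 == pytest.approx(I2)


class TestSimulateEscape:
    def test_zero_deformation_stays_at_rest(self, profile):
        from escapeswim.body3d import planar_motion_from_midlines
        L = profile.standard_length
        straight = np.stack([np.linspace(0, L, 301), np.zeros(301)], 1)
        pm = planar_motion_from_midlines([straight] * 30, profile.half_width,
                                         dt=1e-4)
        tr = simulate_escape(pm, FluidParams(), None)
        assert tr.distance_traveled() < 1e-3 * L * 1e-3

    def test_body_leaving_domain_raises(self, water_motion):
        from escapeswim.flowsolver import SolverConfig
        cfg = SolverConfig(nx=48, domain=0.004)  # body barely fits
        with pytest.raises(RuntimeError, match="boundary"):
            simulate_escape(water_motion, FluidParams(), cfg)
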