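"""Mechanical power, work, cost of transport, and wake diagnostics.

All quantities follow the conventions of the escape-swim pipeline: the
instantaneous power is the traction-power surface integral
P = -surface_integral (T.n).us dS (positive when the body works on the
fluid), total work is its time integral over the six-movement window, the
cost of transport is work per cumulative center-of-mass distance, and the
Reynolds number uses the mean speed over the six simulated tail beats and
the body length. Trace smoothing combines a Savitzky-Golay filter with
spline resampling; power is additionally averaged over a 1 ms window.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splrep
from scipy.signal import savgol_filter

from .flowsolver import (FlowState, FluidParams, SolidState,
                         instantaneous_power_2d)

__all__ = [
    "instantaneous_power",
    "total_energy",
    "cost_of_transport",
    "froude_efficiency",
    "reynolds",
    "vorticity",
    "q_criterion",
    "enstrophy",
    "smooth_trace",
    "smooth_power",
]


def instantaneous_power(flow: FlowState, solid: SolidState,
                        params: FluidParams, depth: float = 0.622e-3) -> float:
    """Mechanical power the body exerts on the fluid (W).

    The 2D traction-power integral (per unit span) is converted with the
    body span ``depth``.
    """
    return instantaneous_power_2d(flow, solid, params) * depth


def total_energy(P: np.ndarray, dt: float, ti: float = None, tf: float = None,
                 rule: str = "riemann") -> float:
    """Total work E = integral of P over [ti, tf] (J).

    ``rule`` selects the Riemann sum (default, matching the discrete
    formulation E ~ sum P_i dt) or the trapezoid rule.
    """
    P = np.asarray(P, dtype=float)
    t = np.arange(P.size) * dt
    if ti is None:
        ti = t[0]
    if tf is None:
        tf = t[-1]
    if not ti < tf:
        raise ValueError("empty integration window")
    sel = (t >= ti - 1e-15) & (t <= tf + 1e-15)
    if not sel.any():
        raise ValueError("window outside the trace")
    Pw = P[sel]
    if rule == "riemann":
        return float(Pw.sum() * dt)
    if rule == "trapezoid":
        return float(np.trapezoid(Pw, dx=dt))
    raise ValueError(f"unknown rule {rule!r}")


def cost_of_transport(E: float, d_total: float) -> float:
    """CoT = E / d_total (J/m); requires a positive cumulative distance."""
    if d_total <= 0:
        raise ValueError("cost of transport undefined for zero distance")
    return E / d_total


def froude_efficiency(W_useful: float, W_total: float) -> float:
    """eta_Fr = W_useful / W_total (defined for prescribed harmonic tests)."""
    if W_total <= 0:
        raise ValueError("total work must be positive")
    return W_useful / W_total


def reynolds(params: FluidParams, V_mean: float, L: float) -> float:
    """Re = rho V_mean L / mu with the body length L (m)."""
    if V_mean < 0 or L < 0:
        raise ValueError("V_mean and L must be nonnegative")
    return params.rho * V_mean * L / params.mu


def _center_gradients(flow: FlowState):
    uc, vc = flow.centered_velocity()
    dudy, dudx = np.gradient(uc, flow.grid.dx)
    dvdy, dvdx = np.gradient(vc, flow.grid.dx)
    return dudx, dudy, dvdx, dvdy


def vorticity(flow: FlowState) -> np.ndarray:
    """Out-of-plane vorticity omega_z = dv/dx - du/dy at cell centers."""
    dudx, dudy, dvdx, dvdy = _center_gradients(flow)
    return dvdx - dudy


def q_criterion(flow: FlowState) -> np.ndarray:
    """Q = (||Omega||_F^2 - ||S||_F^2) / 2 of the velocity gradient.

    Omega and S are the antisymmetric (rotation) and symmetric (strain)
    parts; positive Q marks rotation-dominated (vortex) regions. Reported
    per unit depth in 2D.
    """
    dudx, dudy, dvdx, dvdy = _center_gradients(flow)
    omega = 0.5 * (dvdx - dudy)
    s_off = 0.5 * (dudy + dvdx)
    norm_rot = 2.0 * omega**2
    norm_strain = dudx**2 + dvdy**2 + 2.0 * s_off**2
    return 0.5 * (norm_rot - norm_strain)


def enstrophy(flow: FlowState, exclude_chi: np.ndarray | None = None) -> float:
    """Integral of |vorticity|^2 over the domain (per unit depth)."""
    w = vorticity(flow) ** 2
    if exclude_chi is not None:
        w = w * (1.0 - exclude_chi)
    return float(w.sum() * flow.grid.dx**2)


def smooth_trace(series: np.ndarray, dt: float, kind: str = "savgol_spline",
                 window: int = 11, order: int = 3) -> np.ndarray:
    """Smooth a kinematic/energetic time series.

    ``savgol_spline`` (default) applies a Savitzky-Golay filter and then a
    cubic smoothing-spline resampling on the original time base; ``savgol``
    skips the spline pass. Raises when the series is shorter than the
    window.
    """
    series = np.asarray(series, dtype=float)
    if series.size <= window:
        raise ValueError("series shorter than the smoothing window")
    out = savgol_filter(series, window, order)
    if kind == "savgol":
        return out
    if kind == "savgol_spline":
        resid_var = float(np.var(out - series))
        if resid_var == 0.0:
            return out
        t = np.arange(series.size) * dt
        tck = splrep(t, out, s=series.size * resid_var * 0.1)
        return np.asarray(splev(t, tck))
    raise ValueError(f"unknown smoothing kind {kind!r}")


def smooth_power(P: np.ndarray, dt: float,
                 window_s: float = 1e-3) -> np.ndarray:
    """Moving-average power over ``window_s`` (default one millisecond)."""
    P = np.asarray(P, dtype=float)
    window = max(1, int(round(window_s / dt)))
    if window >= P.size:
        raise ValueError("window longer than the power series")
    return ndimage.uniform_filter1d(P, size=window, mode="nearest")
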