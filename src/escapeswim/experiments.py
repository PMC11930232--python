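"""In-silico viscosity experiments and their linear-regression summaries.

Three protocols mirror the study design:

* realistic sweep -- body movements "recorded" at each viscosity (here:
  synthetic kinematics whose beat frequency slows with viscosity while the
  bend amplitudes stay fixed) are each simulated at their own viscosity;
* virtual sweep -- one body movement recorded in water is simulated at every
  viscosity with the kinematics held fixed;
* frequency rescaling -- a body movement's time axis is dilated (e.g. a 30%
  beat-frequency reduction) with the per-frame shapes untouched.

Each run is summarized over the six-movement window (C-bend, counterbend,
four fast-swim beats; the window ends half a beat period after the sixth
curvature maximum) and sweep tables are fitted by ordinary least squares
with Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .body3d import PlanarBodyMotion
from .energetics import cost_of_transport, reynolds, smooth_power, total_energy
from .flowsolver import FluidParams, SimulationTrace, SolverConfig, simulate_escape
from .midline import stage_window

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "RunSummary",
    "summarize_run",
    "regress_linear",
    "rescale_frequency",
    "run_virtual_sweep",
    "run_realistic_sweep",
]

PAPER_VISCOSITIES_MPAS = (0.83, 1.1, 2.3, 5.0, 10.0, 15.0)


@dataclass
class ExperimentConfig:
    """Sweep protocol: viscosities in mPa s, solver config, rescale factor."""

    viscosities_mpas: tuple = PAPER_VISCOSITIES_MPAS
    frequency_factor: float = 0.7
    solver: SolverConfig = field(default_factory=SolverConfig)
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.viscosities_mpas):
            raise ValueError("viscosities must be positive")
        if not 0.0 < self.frequency_factor <= 1.0:
            raise ValueError("frequency_factor must be in (0, 1]")


@dataclass
class RunSummary:
    """Per-run energetic and kinematic descriptors (SI; power in W)."""

    mu_mpas: float
    energy_j: float
    mean_power_w: float
    cot_j_per_m: float
    distance_m: float
    mean_velocity_m_s: float
    reynolds: float
    duration_s: float


@dataclass
class SweepResult:
    """Summary table (one row per run) plus linear regressions vs viscosity."""

    table: pd.DataFrame
    regressions: dict

    def r_squared(self, quantity: str) -> float:
        return self.regressions[quantity]["r_squared"]


def regress_linear(x, y) -> dict:
    """Ordinary least squares y = a x + b with Pearson correlation.

    Returns slope, intercept, R^2, Pearson r and the two-sided t-test
    p-value. Requires n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "pearson_r": float(res.rvalue),
        "p_value": float(res.pvalue),
    }


def summarize_run(trace: SimulationTrace, params: FluidParams,
                  body_length_m: float) -> RunSummary:
    """Six-movement-window energetics of one simulation trace.

    The window runs from motion onset to half a beat period past the sixth
    |head-tail angle| maximum; power is 1 ms-averaged before integration.
    """
    dt = float(np.median(np.diff(trace.t)))
    _, t_end = stage_window(trace.head_tail_angle, dt)
    i_end = min(trace.t.size - 1, int(round(t_end / dt)))
    P = smooth_power(trace.P, dt)
    E = total_energy(P[: i_end + 1], dt)
    step = np.hypot(*np.diff(trace.cm, axis=0).T)
    d = float(step[:i_end].sum())
    T = i_end * dt
    v_mean = d / T if T > 0 else 0.0
    return RunSummary(
        mu_mpas=params.mu * 1e3,
        energy_j=E,
        mean_power_w=E / T if T > 0 else 0.0,
        cot_j_per_m=cost_of_transport(E, d),
        distance_m=d,
        mean_velocity_m_s=v_mean,
        reynolds=reynolds(params, v_mean, body_length_m),
        duration_s=T,
    )


def rescale_frequency(motion: PlanarBodyMotion,
                      factor: float) -> PlanarBodyMotion:
    """Dilate the time axis by 1/factor, keeping per-frame shapes unchanged.

    The sequence is resampled back to the original dt (linear interpolation
    between frames), so a factor of 0.7 gives a 30% lower tail-beat
    frequency over a 1/0.7 longer duration; deformation velocities scale by
    the factor.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1.0:
        return motion
    n_old = motion.n_frames
    T_new = motion.t[-1] / factor
    n_new = int(round(T_new / motion.dt)) + 1
    t_new = np.arange(n_new) * motion.dt
    src = np.clip(t_new * factor, 0.0, motion.t[-1])

    def interp_frames(arr: np.ndarray) -> np.ndarray:
        flat = arr.reshape(n_old, -1)
        out = np.empty((n_new, flat.shape[1]))
        for j in range(flat.shape[1]):
            out[:, j] = np.interp(src, motion.t, flat[:, j])
        return out.reshape((n_new,) + arr.shape[1:])

    boundary = interp_frames(motion.boundary)
    interior = interp_frames(motion.interior)
    boundary_vel = interp_frames(motion.boundary_vel) * factor
    interior_vel = interp_frames(motion.interior_vel) * factor
    ht = np.interp(src, motion.t, motion.head_tail_angle)
    return PlanarBodyMotion(
        t=t_new, boundary=boundary, boundary_vel=boundary_vel,
        interior=interior, interior_vel=interior_vel,
        weights=motion.weights, dt=motion.dt,
        standard_length=motion.standard_length,
        head_tail_angle=ht, mean_half_width=motion.mean_half_width)


def _sweep_table(rows: list[RunSummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def _sweep_regressions(table: pd.DataFrame) -> dict:
    out = {}
    x = table["mu_mpas"].to_numpy()
    if np.unique(x).size < 3:
        return out
    for col in ("mean_power_w", "energy_j", "cot_j_per_m",
                "distance_m", "mean_velocity_m_s"):
        out[col] = regress_linear(x, table[col].to_numpy())
    return out


def run_virtual_sweep(motion: PlanarBodyMotion,
                      cfg: ExperimentConfig | None = None) -> SweepResult:
    """Simulate one fixed body movement at every viscosity of the sweep.

    The kinematic input is identical across runs; only the fluid viscosity
    changes ("computational enhancement of viscosity"). Regressions of mean
    power, energy and CoT against viscosity are attached when >= 3
    viscosities are given (otherwise skipped with a warning).
    """
    if cfg is None:
        cfg = ExperimentConfig()
    rows = []
    for mu in cfg.viscosities_mpas:
        params = FluidParams(rho=cfg.rho, mu=mu * 1e-3)
        trace = simulate_escape(motion, params, cfg.solver)
        rows.append(summarize_run(trace, params,
                                  motion.standard_length * 1e-3))
    table = _sweep_table(rows)
    if len(cfg.viscosities_mpas) < 3:
        import warnings
        warnings.warn("fewer than 3 viscosities: regression skipped")
        return SweepResult(table=table, regressions={})
    return SweepResult(table=table, regressions=_sweep_regressions(table))


def run_realistic_sweep(motions: dict[float, PlanarBodyMotion],
                        cfg: ExperimentConfig | None = None) -> SweepResult:
    """Simulate each body movement at the viscosity it was recorded in.

    ``motions`` maps viscosity (mPa s) to the body movement recorded at that
    viscosity; each run uses its own label as the simulation viscosity.
    """
    if cfg is None:
        cfg = ExperimentConfig()
    if not motions:
        raise ValueError("no labeled motions given")
    rows = []
    for mu, motion in sorted(motions.items()):
        if mu is None or mu <= 0:
            raise ValueError("every motion needs a positive viscosity label")
        params = FluidParams(rho=cfg.rho, mu=mu * 1e-3)
        trace = simulate_escape(motion, params, cfg.solver)
        rows.append(summarize_run(trace, params,
                                  motion.standard_length * 1e-3))
    table = _sweep_table(rows)
    regs = _sweep_regressions(table) if len(motions) >= 3 else {}
    return SweepResult(table=table, regressions=regs)


def adapted_cstart_params(mu_mpas: float, base=None, seed: int = 0,
                          exponent: float = 0.2):
    """Synthetic viscosity-adapted C-start parameters.

    Emulates the observed behavioral adaptation: the tail bend/beat
    frequency decreases with viscosity -- modeled here as
    f = f0 (mu0 / mu)^exponent with mu0 = 0.83 mPa s -- while the bend and
    beat amplitudes stay fixed. Stage durations stretch with the inverse
    frequency so the sequence still spans six movements.
    """
    from dataclasses import replace as dc_replace

    from .synthgen import CStartParams

    if base is None:
        base = CStartParams()
    scale = (0.83 / mu_mpas) ** exponent
    d1, d2, _ = base.stage_durations
    f = base.beat_frequency * scale
    fast_ms = 1000.0 * base.n_fast_beats / (2.0 * f)
    return dc_replace(base, beat_frequency=f,
                      stage_durations=(d1 / scale, d2 / scale, fast_ms),
                      seed=seed)
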