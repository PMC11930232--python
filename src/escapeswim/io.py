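"""Readers and writers for the pipeline's on-disk formats.

Movies and slice stacks travel as multi-page TIFF; traces and summaries as
CSV; flow snapshots as legacy-ASCII VTK structured points (u, v, p,
vorticity, Q, chi); body meshes as ASCII PLY.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .body3d import BodyMesh
from .containers import FrameStack, RigidTrace, SliceStack
from .flowsolver import FlowState, SimulationTrace


def write_frame_stack(path, stack: FrameStack) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.uint8),
                     metadata={"dt_s": stack.dt,
                               "pixel_scale_mm": stack.pixel_scale})


def read_frame_stack(path, dt: float, pixel_scale: float) -> FrameStack:
    frames = tifffile.imread(path)
    return FrameStack(frames=frames, dt=dt, pixel_scale=pixel_scale)


def write_slice_stack(path, stack: SliceStack) -> None:
    tifffile.imwrite(path, stack.images.astype(np.uint8) * 255)


def write_rigid_trace(path, trace: RigidTrace) -> None:
    pd.DataFrame({
        "frame": np.arange(trace.t.size),
        "t_s": trace.t,
        "cm_x_mm": trace.cm[:, 0],
        "cm_y_mm": trace.cm[:, 1],
        "alpha_deg": trace.alpha,
    }).to_csv(path, index=False)


def write_midlines_csv(path, midlines) -> None:
    rows = []
    for f, m in enumerate(midlines):
        pts = m.points if hasattr(m, "points") else np.asarray(m)
        for i, (x, y) in enumerate(pts):
            rows.append((f, i, x, y))
    pd.DataFrame(rows, columns=["frame", "s_index", "x_mm", "y_mm"]
                 ).to_csv(path, index=False)


def write_trace_csv(path, trace: SimulationTrace) -> None:
    pd.DataFrame({
        "t_s": trace.t,
        "cm_x_m": trace.cm[:, 0],
        "cm_y_m": trace.cm[:, 1],
        "theta_rad": trace.theta,
        "Fx_N_per_m": trace.F[:, 0],
        "Fy_N_per_m": trace.F[:, 1],
        "M_N": trace.M,
        "P_w": trace.P,
        "head_tail_angle_deg": trace.head_tail_angle,
    }).to_csv(path, index=False)


def write_vtk_snapshot(path, flow: FlowState,
                       chi: np.ndarray | None = None) -> None:
    """Legacy-ASCII VTK structured-points snapshot of a flow state."""
    from .energetics import q_criterion, vorticity

    grid = flow.grid
    uc, vc = flow.centered_velocity()
    om = vorticity(flow)
    q = q_criterion(flow)
    fields = {"u": uc, "v": vc, "p": flow.p, "vorticity": om, "Q": q}
    if chi is not None:
        fields["chi"] = chi
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"flow snapshot t={flow.t:.6e}\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {grid.nx} {grid.ny} 1\n")
        fh.write(f"ORIGIN {grid.x0 + grid.dx / 2} {grid.y0 + grid.dx / 2} 0\n")
        fh.write(f"SPACING {grid.dx} {grid.dx} 1\n")
        fh.write(f"POINT_DATA {grid.nx * grid.ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.ravel()[:, None], fmt="%.6e")


def write_ply_mesh(path, mesh: BodyMesh) -> None:
    """ASCII PLY of the Lagrangian marker surface (quad faces as triangles)."""
    m = mesh.markers
    n_ax, n_c = m.shape[:2]
    verts = m.reshape(-1, 3)
    faces = []
    for i in range(n_ax - 1):
        for j in range(n_c):
            j2 = (j + 1) % n_c
            a = i * n_c + j
            b = i * n_c + j2
            c = (i + 1) * n_c + j2
            d = (i + 1) * n_c + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        np.savetxt(fh, verts, fmt="%.6f")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
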