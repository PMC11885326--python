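"""File I/O for geometries, waveforms, references and fields.

Surfaces travel as STL/OBJ/PLY through trimesh; centerlines as CSV with
x,y,z (and optional diameter) columns in cm; landmarks as a JSON map of
name -> arclength (cm); inflow waveforms as CSV with time_s, flow_cm3_s
columns.  Velocity-field snapshots export as legacy-VTK ASCII structured
point-vector files (written directly; the format is a short plain-text
header plus point and vector lists).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .anatomy import AortaSurface, Centerline
from .flowfield import VelocityField
from .windkessel import InflowWaveform

__all__ = [
    "save_surface",
    "load_surface",
    "save_centerline",
    "load_centerline",
    "save_landmarks",
    "load_landmarks",
    "save_waveform",
    "load_waveform",
    "export_field_vtk",
]


def save_surface(surf: AortaSurface, path) -> None:
    path = Path(path)
    mesh = surf.as_trimesh()
    ftype = "stl_ascii" if path.suffix.lower() == ".stl" else None
    mesh.export(path, file_type=ftype)
    lm_path = path.with_suffix(".landmarks.json")
    save_landmarks(surf.landmarks, lm_path)


def load_surface(path, landmarks: Optional[Dict[str, float]] = None) -> AortaSurface:
    path = Path(path)
    mesh = trimesh.load_mesh(path)
    if landmarks is None:
        lm_path = path.with_suffix(".landmarks.json")
        landmarks = load_landmarks(lm_path) if lm_path.exists() else {}
    return AortaSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces), landmarks)


def save_centerline(cl: Centerline, path) -> None:
    pd.DataFrame(
        {
            "x": cl.points[:, 0],
            "y": cl.points[:, 1],
            "z": cl.points[:, 2],
            "diameter_cm": cl.local_diameter,
        }
    ).to_csv(path, index=False)


def load_centerline(path) -> Centerline:
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    d = df["diameter_cm"].to_numpy(dtype=float) if "diameter_cm" in df else 1.0
    return Centerline.from_points(pts, d)


def save_landmarks(landmarks: Dict[str, float], path) -> None:
    Path(path).write_text(json.dumps({k: float(v) for k, v in landmarks.items()}, indent=1))


def load_landmarks(path) -> Dict[str, float]:
    return {k: float(v) for k, v in json.loads(Path(path).read_text()).items()}


def save_waveform(w: InflowWaveform, path) -> None:
    pd.DataFrame({"time_s": w.time, "flow_cm3_s": w.flow}).to_csv(path, index=False)


def load_waveform(path) -> InflowWaveform:
    df = pd.read_csv(path)
    return InflowWaveform(df["time_s"].to_numpy(float), df["flow_cm3_s"].to_numpy(float))


def export_field_vtk(
    field: VelocityField,
    path,
    times: Optional[Sequence[float]] = None,
    n_per_ring: int = 16,
    n_rings: int = 120,
    n_radial: int = 4,
) -> None:
    """Write velocity snapshots as legacy-VTK ASCII polydata point clouds.

    One file per frame (suffix _NNN.vtk); points are a tube lattice along
    the centerline with a VECTORS attribute 'velocity' (cm/s).  Plain-text
    output, viewable in ParaView and similar tools.
    """
    path = Path(path)
    cl = field.centerline
    s_vals = np.linspace(0.0, cl.length, n_rings)
    e_y = np.array([0.0, 1.0, 0.0])
    pts = []
    for s in s_vals:
        p0 = cl.point_at(s)
        t = cl.tangent_at(s)
        e1 = np.cross(e_y, t)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        R = 0.5 * float(cl.diameter_at(s))
        for rf in (np.arange(n_radial) + 0.5) / n_radial:
            for phi in np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False):
                pts.append(p0 + rf * R * (np.cos(phi) * e1 + np.sin(phi) * e2))
    pts = np.asarray(pts)

    if times is None:
        times = field.frame_times
    for i, t in enumerate(times):
        vel = field.velocity(pts, float(t))
        fname = path.parent / f"{path.stem}_{i:03d}.vtk"
        with open(fname, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"velocity field t={t:.4f}s\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(pts)} float\n")
            np.savetxt(fh, pts, fmt="%.5f")
            fh.write(f"POINT_DATA {len(pts)}\nVECTORS velocity float\n")
            np.savetxt(fh, vel, fmt="%.5f")
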