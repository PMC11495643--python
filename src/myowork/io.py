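"""File formats: mesh sequences, pressure traces, strain/work tables.

Surfaces travel either as one mesh file per frame (OBJ or PLY, via
trimesh) with a JSON sidecar for frame times and landmarks, or as a single
reference mesh plus a long-format CSV displacement table
(vertex, frame, dx, dy, dz). Pressure traces are two-column CSV
(time_ms, pressure_kpa or pressure_mmhg; the header names the unit).
Work maps can additionally be rendered to legacy-ASCII VTK polydata with
per-cell work densities for visualization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import EndocardialSurface
from .strain import StrainField
from .stress import MMHG_TO_KPA, PressureWaveform
from .work import WorkMap


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def _sidecar(surface: EndocardialSurface) -> dict:
    return {
        "frame_times_ms": surface.frame_times.tolist(),
        "apex_point_mm": surface.apex_point.tolist(),
        "base_centroid_mm": surface.base_centroid.tolist(),
        "long_axis": surface.long_axis.tolist(),
    }


def write_surface_frames(surface: EndocardialSurface, directory, fmt: str = "obj") -> list[Path]:
    """One mesh file per frame plus ``surface.json`` with times/landmarks."""
    if fmt not in ("obj", "ply"):
        raise IOError_(f"unsupported mesh format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in range(surface.n_frames):
        mesh = trimesh.Trimesh(vertices=surface.vertices[f],
                               faces=surface.triangles, process=False)
        p = directory / f"frame_{f:03d}.{fmt}"
        export = mesh.export(file_type=fmt)
        mode = "wb" if isinstance(export, bytes) else "w"
        with open(p, mode) as fh:
            fh.write(export)
        paths.append(p)
    (directory / "surface.json").write_text(json.dumps(_sidecar(surface), indent=1))
    return paths


def read_surface_frames(directory) -> EndocardialSurface:
    """Load a per-frame mesh directory written by :func:`write_surface_frames`."""
    directory = Path(directory)
    meta = json.loads((directory / "surface.json").read_text())
    files = sorted(p for p in directory.iterdir()
                   if p.suffix in (".obj", ".ply") and p.stem.startswith("frame_"))
    if not files:
        raise IOError_(f"no frame meshes found in {directory}")
    meshes = [trimesh.load(p, process=False) for p in files]
    tris = np.asarray(meshes[0].faces)
    verts = np.stack([np.asarray(m.vertices) for m in meshes])
    return EndocardialSurface(
        vertices=verts, triangles=tris,
        frame_times=np.asarray(meta["frame_times_ms"], float),
        apex_point=np.asarray(meta["apex_point_mm"], float),
        base_centroid=np.asarray(meta["base_centroid_mm"], float),
        long_axis=np.asarray(meta["long_axis"], float),
    )


def write_surface_displacements(surface: EndocardialSurface, directory) -> None:
    """Compact form: reference OBJ + displacement CSV + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref = trimesh.Trimesh(vertices=surface.vertices[0], faces=surface.triangles, process=False)
    (directory / "reference.obj").write_text(ref.export(file_type="obj"))
    disp = surface.vertices[1:] - surface.vertices[0][None]
    n_f, n_v, _ = disp.shape
    df = pd.DataFrame({
        "vertex": np.tile(np.arange(n_v), n_f),
        "frame": np.repeat(np.arange(1, n_f + 1), n_v),
        "dx": disp[:, :, 0].ravel(),
        "dy": disp[:, :, 1].ravel(),
        "dz": disp[:, :, 2].ravel(),
    })
    df.to_csv(directory / "displacements.csv", index=False, float_format="%.6g")
    (directory / "surface.json").write_text(json.dumps(_sidecar(surface), indent=1))


def read_surface_displacements(directory) -> EndocardialSurface:
    directory = Path(directory)
    meta = json.loads((directory / "surface.json").read_text())
    ref = trimesh.load(directory / "reference.obj", process=False)
    df = pd.read_csv(directory / "displacements.csv")
    n_v = len(ref.vertices)
    frames = sorted(df["frame"].unique())
    verts = [np.asarray(ref.vertices)]
    for f in frames:
        sub = df[df["frame"] == f].sort_values("vertex")
        if len(sub) != n_v:
            raise IOError_(f"frame {f}: {len(sub)} displacement rows for {n_v} vertices")
        verts.append(verts[0] + sub[["dx", "dy", "dz"]].to_numpy())
    return EndocardialSurface(
        vertices=np.stack(verts), triangles=np.asarray(ref.faces),
        frame_times=np.asarray(meta["frame_times_ms"], float),
        apex_point=np.asarray(meta["apex_point_mm"], float),
        base_centroid=np.asarray(meta["base_centroid_mm"], float),
        long_axis=np.asarray(meta["long_axis"], float),
    )


# ---------------------------------------------------------------------------
# pressure
# ---------------------------------------------------------------------------


def write_pressure_csv(wave: PressureWaveform, path) -> None:
    pd.DataFrame({"time_ms": wave.times, "pressure_kpa": wave.pressures}).to_csv(
        path, index=False, float_format="%.6g")


def read_pressure_csv(path, label: str = "measured") -> PressureWaveform:
    """Read a two-column pressure CSV; the header names the unit.

    Accepts ``pressure_kpa`` or ``pressure_mmhg`` (converted at
    1 mmHg = 0.133322 kPa).
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_ms" not in cols:
        raise IOError_("pressure CSV needs a time_ms column")
    t = df[cols["time_ms"]].to_numpy(float)
    if "pressure_kpa" in cols:
        p = df[cols["pressure_kpa"]].to_numpy(float)
    elif "pressure_mmhg" in cols:
        p = df[cols["pressure_mmhg"]].to_numpy(float) * MMHG_TO_KPA
    else:
        raise IOError_("pressure CSV needs pressure_kpa or pressure_mmhg")
    return PressureWaveform(times=t, pressures=p, label=label)


# ---------------------------------------------------------------------------
# strain / work / metrics tables
# ---------------------------------------------------------------------------


def strain_to_frame(field: StrainField) -> pd.DataFrame:
    """Long-format strain table (unit_id, frame_time_ms, strain)."""
    n_u, n_f = field.values.shape
    return pd.DataFrame({
        "unit_id": np.repeat(field.unit_ids, n_f),
        "frame_time_ms": np.tile(field.frame_times, n_u),
        "strain": field.values.ravel(),
    })


def work_map_to_frame(workmap: WorkMap) -> pd.DataFrame:
    return pd.DataFrame({
        "unit_id": workmap.unit_ids,
        "segment": workmap.segment,
        "region": workmap.region,
        "work_kpa": workmap.work,
        "weight": workmap.weights,
        "weight_kind": workmap.weight_kind,
        "state": workmap.state,
        "method": workmap.method,
    })


def write_work_map_vtk(workmap: WorkMap, surface: EndocardialSurface, path,
                       frame: int = 0) -> None:
    """Legacy-ASCII VTK polydata with per-cell signed work densities.

    Only cells present in the map (patches with valid strain) are written.
    """
    if workmap.resolution != "patch":
        raise IOError_("VTK export expects a patch-resolution work map")
    v = surface.vertices[frame]
    tris = surface.triangles[np.asarray(workmap.unit_ids, dtype=np.intp)]
    lines = [
        "# vtk DataFile Version 3.0",
        f"myowork map method={workmap.method} state={workmap.state}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} float",
    ]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in v]
    lines.append(f"POLYGONS {len(tris)} {4 * len(tris)}")
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in tris]
    lines.append(f"CELL_DATA {len(tris)}")
    lines.append("SCALARS work_kpa float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{w:.6g}" for w in workmap.work]
    lines.append("SCALARS segment int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(s)) for s in workmap.segment]
    Path(path).write_text("\n".join(lines) + "\n")


def metrics_to_frame(records: list[dict]) -> pd.DataFrame:
    """Tidy metrics table: one row per (patient, state, method, metric)."""
    rows = []
    for rec in records:
        base = {k: rec[k] for k in ("patient", "state", "method")}
        for metric, value in rec["metrics"].items():
            rows.append({**base, "metric": metric, "value": value})
    return pd.DataFrame(rows)
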