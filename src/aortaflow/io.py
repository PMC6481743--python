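"""File interchange: legacy-ASCII VTK output, waveform CSV, plane-map I/O.

Meshes and nodal fields are written as legacy ASCII VTK unstructured grids
(one file per phase plus a JSON manifest) readable by ParaView; waveforms
are 2-column CSV; plane velocity maps are stored as a flat directory of
per-phase CSV matrices with a JSON sidecar holding the grid geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .acquisition import PlaneSpec, PlaneVelocityMap
from .fields import FlowWaveform, TimeVaryingField
from .mesh import TubeMesh

_VTK_HEX = 12


def write_vtk(path, mesh: TubeMesh, point_data: dict | None = None,
              title: str = "aortaflow tube mesh") -> None:
    """Write the mesh (plus optional per-node scalar/vector data) as a
    legacy ASCII VTK unstructured grid."""
    path = Path(path)
    pts = mesh.node_positions
    cells = mesh.cells
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(title[:255] + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        np.savetxt(f, pts, fmt="%.10g")
        f.write(f"CELLS {len(cells)} {len(cells) * 9}\n")
        np.savetxt(f, np.column_stack([np.full(len(cells), 8), cells]), fmt="%d")
        f.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(f, np.full(len(cells), _VTK_HEX), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.10g")
                else:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.10g")


def write_field_series(directory, fld: TimeVaryingField, prefix: str = "phase") -> None:
    """One VTK file per phase plus an index manifest (times, period)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = []
    for i in range(fld.n_times):
        name = f"{prefix}_{i:04d}.vtk"
        write_vtk(d / name, fld.mesh, {"velocity": fld.velocity[i]})
        names.append(name)
    (d / "manifest.json").write_text(json.dumps(
        {"files": names, "times_s": fld.times.tolist(), "period_s": fld.period},
        indent=2))


def write_waveform_csv(path, waveform: FlowWaveform) -> None:
    with Path(path).open("w") as f:
        f.write("t_s,Q_m3s\n")
        np.savetxt(f, np.column_stack([waveform.times, waveform.q]),
                   fmt="%.10g", delimiter=",")


def read_waveform_csv(path, period: float, systolic_markers=None) -> FlowWaveform:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if systolic_markers is None:
        systolic_markers = np.array([])
    return FlowWaveform(times=data[:, 0], q=data[:, 1], period=period,
                        systolic_markers=np.asarray(systolic_markers))


def save_plane_map(directory, pmap: PlaneVelocityMap) -> None:
    """Flat-directory layout: meta.json + per-phase CSV component matrices."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_size_m": pmap.pixel_size,
        "slab_thickness_m": pmap.slab_thickness,
        "phases_s": pmap.phases.tolist(),
        "period_s": pmap.period,
        "origin_m": pmap.plane.origin.tolist(),
        "axis_u": pmap.plane.axis_u.tolist(),
        "axis_v": pmap.plane.axis_v.tolist(),
        "venc_ms": pmap.venc.tolist(),
        "shape": list(pmap.shape),
        "metadata": {k: v for k, v in pmap.metadata.items()
                     if isinstance(v, (int, float, str, type(None)))},
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(d / "lumen_mask.csv", pmap.lumen_mask.astype(int), fmt="%d", delimiter=",")
    for comp, arr in (("u", pmap.velocity_u), ("v", pmap.velocity_v), ("w", pmap.velocity_w)):
        for i in range(arr.shape[0]):
            np.savetxt(d / f"vel_{comp}_{i:04d}.csv", arr[i], fmt="%.10g", delimiter=",")


def load_plane_map(directory) -> PlaneVelocityMap:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    ny, nx = meta["shape"]
    n_phases = len(meta["phases_s"])
    comps = {}
    for comp in ("u", "v", "w"):
        comps[comp] = np.stack([
            np.loadtxt(d / f"vel_{comp}_{i:04d}.csv", delimiter=",").reshape(ny, nx)
            for i in range(n_phases)
        ])
    mask = np.loadtxt(d / "lumen_mask.csv", delimiter=",").reshape(ny, nx).astype(bool)
    plane = PlaneSpec(origin=np.array(meta["origin_m"]),
                      axis_u=np.array(meta["axis_u"]),
                      axis_v=np.array(meta["axis_v"]))
    return PlaneVelocityMap(
        plane=plane, pixel_size=meta["pixel_size_m"],
        slab_thickness=meta["slab_thickness_m"],
        phases=np.array(meta["phases_s"]), period=meta["period_s"],
        velocity_u=comps["u"], velocity_v=comps["v"], velocity_w=comps["w"],
        lumen_mask=mask, venc=np.array(meta["venc_ms"]),
        metadata=meta.get("metadata", {}),
    )
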