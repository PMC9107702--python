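"""Text-format output: legacy VTK, Gmsh MSH, Nastran bulk, CSV, npz.

Everything written here is plain text except the npz checkpoints (numpy's
own container, for restart/scratch use).  Field output uses the legacy
ASCII VTK unstructured-grid format, readable by ParaView/VisIt; meshes
round-trip through Gmsh MSH v2.2 and export to Nastran bulk data (the
exchange format used by common meshing tools).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fem.mesh import SimplexMesh

__all__ = ["write_vtk", "write_msh", "read_msh", "write_nas",
           "write_flowrates_csv", "write_particles_csv", "save_series",
           "load_series", "write_geometry_metadata"]


def write_vtk(path, mesh: SimplexMesh, point_data: dict | None = None,
              cell_data: dict | None = None):
    """Legacy ASCII VTK unstructured grid (P1 vertices + simplices).

    Point data given at P2 nodes is restricted to the vertices.
    """
    path = Path(path)
    d = mesh.dim
    npts = mesh.n1
    X = np.zeros((npts, 3))
    X[:, :d] = mesh.X1
    vtk_type = 5 if d == 2 else 10       # triangle / tetra
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\npvsporo output\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {npts} double\n")
        np.savetxt(f, X, fmt="%.9e")
        nc = mesh.n_cells
        nv = d + 1
        f.write(f"CELLS {nc} {nc * (nv + 1)}\n")
        np.savetxt(f, np.column_stack(
            [np.full(nc, nv), mesh.cells]), fmt="%d")
        f.write(f"CELL_TYPES {nc}\n")
        np.savetxt(f, np.full(nc, vtk_type), fmt="%d")
        wrote_pd = False
        for name, arr in (point_data or {}).items():
            arr = np.asarray(arr)[:npts]
            if not wrote_pd:
                f.write(f"POINT_DATA {npts}\n")
                wrote_pd = True
            if arr.ndim == 1:
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.9e")
            else:
                V = np.zeros((npts, 3))
                V[:, :arr.shape[1]] = arr
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, V, fmt="%.9e")
        wrote_cd = False
        for name, arr in (cell_data or {}).items():
            if not wrote_cd:
                f.write(f"CELL_DATA {nc}\n")
                wrote_cd = True
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.9e")


def write_msh(path, mesh: SimplexMesh):
    """Gmsh MSH v2.2 ASCII; the physical/geometrical tag is the domain."""
    path = Path(path)
    d = mesh.dim
    etype = 2 if d == 2 else 4          # 3-node tri / 4-node tet
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n1}\n")
        for i, x in enumerate(mesh.X1, start=1):
            coords = list(x) + [0.0] * (3 - d)
            f.write(f"{i} {coords[0]:.9e} {coords[1]:.9e} {coords[2]:.9e}\n")
        f.write("$EndNodes\n")
        f.write(f"$Elements\n{mesh.n_cells}\n")
        for i, (cell, dom) in enumerate(zip(mesh.cells, mesh.domain),
                                        start=1):
            nodes = " ".join(str(v + 1) for v in cell)
            f.write(f"{i} {etype} 2 {dom} {dom} {nodes}\n")
        f.write("$EndElements\n")


def read_msh(path) -> SimplexMesh:
    """Read a v2.2 ASCII MSH written by :func:`write_msh`."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    nodes, cells, doms = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(v) for v in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype in (2, 4):
                    cells.append(conn)
                    doms.append(int(parts[3]))
    X = np.asarray(nodes)
    cells = np.asarray(cells, dtype=np.int64)
    d = 2 if cells.shape[1] == 3 else 3
    return SimplexMesh(X[:, :d], cells, np.asarray(doms),
                       metadata={"source": "msh"})


def write_nas(path, mesh: SimplexMesh):
    """Nastran bulk data (small-field GRID/CTETRA or CTRIA3), mm units
    avoided: coordinates written in metres in 8-char fields via CSV-style
    free field."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("$ pvsporo mesh export (free field)\nBEGIN BULK\n")
        for i, x in enumerate(mesh.X1, start=1):
            coords = ",".join(f"{v:.6e}" for v in x)
            pad = "" if mesh.dim == 3 else ",0.0"
            f.write(f"GRID,{i},,{coords}{pad}\n")
        card = "CTETRA" if mesh.dim == 3 else "CTRIA3"
        for i, (cell, dom) in enumerate(zip(mesh.cells, mesh.domain),
                                        start=1):
            conn = ",".join(str(v + 1) for v in cell)
            f.write(f"{card},{i},{dom},{conn}\n")
        f.write("ENDDATA\n")


def write_geometry_metadata(path, mesh: SimplexMesh):
    Path(path).write_text(json.dumps(mesh.summary(), indent=2) + "\n")


def write_flowrates_csv(path, series):
    df = pd.DataFrame({"t": series.times,
                       **{f"Q_{k}": v for k, v in series.flowrates.items()}})
    if series.wall is not None:
        df["an1_um"] = series.wall[:, 0]
        df["dan1_dt_um_s"] = series.wall[:, 1]
    df.to_csv(path, index=False)
    return df


def write_particles_csv(path, ensemble, labels=None):
    nt, n, _ = ensemble.trajectory.shape
    rec = {
        "t": np.repeat(ensemble.times, n),
        "particle": np.tile(np.arange(n), nt),
        "x": ensemble.trajectory[:, :, 0].ravel(),
        "y": ensemble.trajectory[:, :, 1].ravel(),
        "z": ensemble.trajectory[:, :, 2].ravel(),
    }
    if labels is not None:
        rec["region"] = labels.ravel()
    pd.DataFrame(rec).to_csv(path, index=False)


def save_series(path, series):
    """Checkpoint a TimeSeriesOutput (npz; scratch/restart use)."""
    np.savez_compressed(
        path, times=series.times, u=series.u, w=series.w, v_s=series.v_s,
        p=series.p, wall=series.wall if series.wall is not None else
        np.zeros((0, 2)),
        **{f"Q_{k}": v for k, v in series.flowrates.items()})


def load_series(path):
    from .solver import TimeSeriesOutput
    z = np.load(path)
    flow = {k[2:]: z[k] for k in z.files if k.startswith("Q_")}
    wall = z["wall"] if z["wall"].size else None
    return TimeSeriesOutput(times=z["times"], u=z["u"], w=z["w"],
                            v_s=z["v_s"], p=z["p"], flowrates=flow,
                            wall=wall)
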