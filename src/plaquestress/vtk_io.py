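"""Minimal legacy-VTK ASCII export of section meshes and fields.

Writes UNSTRUCTURED_GRID files readable by ParaView/VisIt for visual
inspection of meshes, material regions, displacement and stress fields, and
fiber frames.  Only the small legacy ASCII subset needed here is produced.
"""

from __future__ import annotations

import numpy as np

from .phantom import SectionMesh

VTK_QUAD = 9


def frame_cell_data(mesh: SectionMesh, frames) -> dict[str, np.ndarray]:
    """Per-element (e_r, e_theta, e_z) vector fields for export.

    Elements without a computed frame (outside the wall) get zero vectors.
    """
    out = {}
    for name, arr in (("e_r", frames.e_r), ("e_theta", frames.e_theta),
                      ("e_z", frames.e_z)):
        full = np.zeros((mesh.n_elems, 3))
        full[frames.element_ids] = arr
        out[name] = full
    return out


def write_vtk(
    path,
    mesh: SectionMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    displacements: np.ndarray | None = None,
) -> None:
    """Write a section mesh (optionally deformed) with attached fields."""
    nodes = mesh.nodes if displacements is None else mesh.nodes + displacements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nplaquestress section\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, y in nodes:
            fh.write(f"{x:.9g} {y:.9g} {mesh.station_z:.9g}\n")
        m = mesh.n_elems
        fh.write(f"CELLS {m} {5 * m}\n")
        for q in mesh.quads:
            fh.write(f"4 {q[0]} {q[1]} {q[2]} {q[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join([str(VTK_QUAD)] * m) + "\n")

        def _write_block(kind: str, n: int, data: dict[str, np.ndarray]):
            fh.write(f"{kind} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        v = np.zeros(3)
                        v[: len(row)] = row
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")

        if point_data:
            _write_block("POINT_DATA", len(nodes), point_data)
        cd = {"region": mesh.region.astype(float)}
        if cell_data:
            cd.update(cell_data)
        _write_block("CELL_DATA", m, cd)
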