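"""Legacy-ASCII VTK export of the tetrahedral mesh and solution fields.

The unstructured grid contains the tetrahedra followed by the tagged
facet triangles, with two cell-data arrays: ``subdomain`` (material
region per tet, -1 on triangles) and ``boundary_tag`` (-1 on tets).
"""

from __future__ import annotations

import numpy as np

from .geometry import Mesh

_VTK_TRI = 5
_VTK_TET = 10


def write_vtk(
    path: str,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    include_facets: bool = True,
) -> None:
    """Write an unstructured-grid .vtk file (legacy ASCII, version 2.0).

    Extra per-tet arrays may be passed via cell_data; they are padded
    with zeros on the facet triangles.
    """
    nodes, elems = mesh.nodes, mesh.elems
    facets = mesh.facets if include_facets else np.empty((0, 3), dtype=int)
    n_cells = len(elems) + len(facets)

    lines = [
        "# vtk DataFile Version 2.0",
        "airwayrf mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{x:.9e}" for x in p) for p in nodes]
    size = 5 * len(elems) + 4 * len(facets)
    lines.append(f"CELLS {n_cells} {size}")
    lines += ["4 " + " ".join(map(str, e)) for e in elems]
    lines += ["3 " + " ".join(map(str, f)) for f in facets]
    lines.append(f"CELL_TYPES {n_cells}")
    lines += [str(_VTK_TET)] * len(elems)
    lines += [str(_VTK_TRI)] * len(facets)

    arrays: dict[str, np.ndarray] = {
        "subdomain": np.concatenate(
            [mesh.elem_tag, np.full(len(facets), -1, dtype=np.int32)]),
        "boundary_tag": np.concatenate(
            [np.full(len(elems), -1, dtype=np.int32),
             mesh.facet_tag[:len(facets)]]),
    }
    for name, data in (cell_data or {}).items():
        data = np.asarray(data)
        pad = np.zeros(len(facets), dtype=data.dtype)
        arrays[name] = np.concatenate([data, pad])

    lines.append(f"CELL_DATA {n_cells}")
    for name, data in arrays.items():
        kind = "int" if np.issubdtype(data.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        fmt = "{:d}" if kind == "int" else "{:.9e}"
        lines += [fmt.format(v) for v in data]

    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, data in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9e}" for v in np.asarray(data, dtype=float)]

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
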