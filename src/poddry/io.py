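"""Plain-text output writers: ASCII VTU field snapshots (with a PVD time
series index) and curve/metric files."""

from __future__ import annotations

from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .geometry import AxiMesh


def write_vtu(path, mesh: AxiMesh, point_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write the mesh and optional nodal scalars as an ASCII .vtu file.

    The (r, z) plane is emitted as (x, y, 0); region labels go out as
    integer cell data in geometry-region order.
    """
    path = Path(path)
    n_pts, n_cells = len(mesh.nodes), len(mesh.elements)
    region_code = {reg: i for i, reg in enumerate(mesh.geometry.regions)}
    cell_region = np.array([region_code[r] for r in mesh.region])

    def arr(a, fmt="{:.9g}"):
        return " ".join(fmt.format(v) for v in np.asarray(a).ravel())

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(np.column_stack([mesh.nodes, np.zeros(n_pts)])),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(mesh.elements, "{:d}"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(3 * (np.arange(n_cells) + 1), "{:d}"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full(n_cells, 5), "{:d}"),
        "</DataArray>",
        "</Cells>",
        "<CellData>",
        '<DataArray type="Int32" Name="region" format="ascii">',
        arr(cell_region, "{:d}"),
        "</DataArray>",
        "</CellData>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, values in point_data.items():
            lines.append(
                f'<DataArray type="Float64" Name="{escape(name)}" format="ascii">'
            )
            lines.append(arr(values))
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


def write_pvd(path, timesteps: list[tuple[float, str]]) -> Path:
    """Write a ParaView .pvd index for a VTU time series."""
    path = Path(path)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1">',
        "<Collection>",
    ]
    for t, fname in timesteps:
        lines.append(f'<DataSet timestep="{t:.9g}" file="{escape(str(fname))}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path
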