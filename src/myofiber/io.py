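"""Reading labeled Gmsh meshes and writing ParaView-consumable output.

Supported input: Gmsh ``.msh`` ASCII, versions 2.2 and 4.1, with a single
volumetric element type (tet4 or hex8) and labeled boundary facets
(triangles / quadrilaterals).  Physical-group tags are preferred as facet
labels; elementary-entity tags are the fallback, since both conventions
occur in gmsh-produced meshes.

Output: an XDMF schema file wrapped around an HDF5 heavy-data file
(ParaView's native path), or an ASCII VTU file as a pure-text fallback.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .errors import MeshError, MeshFormatError, MissingLabelsError, UnsupportedMeshError
from .mesh import HEX, TET, FieldBundle, LabeledMesh

# gmsh element type codes
_GMSH_TRI = 2
_GMSH_QUAD = 3
_GMSH_TET = 4
_GMSH_HEX = 5
_NODES_PER_TYPE = {1: 2, 2: 3, 3: 4, 4: 4, 5: 8, 15: 1}


def read_msh(path, scaling_factor: float = 1.0) -> LabeledMesh:
    """Read a labeled Gmsh ASCII mesh.

    Parameters
    ----------
    path : path-like
        ``.msh`` file, ASCII version 2.2 or 4.1.
    scaling_factor : float
        Multiplies every coordinate on read (e.g. ``1e-3`` for a mesh
        authored in millimeters, so the result is in meters).
    """
    if scaling_factor <= 0:
        raise ValueError("scaling_factor must be positive")
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    sections = _split_sections(lines, path)
    if "MeshFormat" not in sections:
        raise MeshFormatError(f"{path}: missing $MeshFormat section")
    fmt = sections["MeshFormat"][0].split()
    version, file_type = fmt[0], int(fmt[1])
    if file_type != 0:
        raise MeshFormatError(f"{path}: binary .msh (file-type {file_type}) not supported")
    if version.startswith("2"):
        if version != "2.2":
            raise MeshFormatError(f"{path}: unsupported .msh version {version}")
        verts, elems = _parse_v2(sections, path)
    elif version == "4.1":
        verts, elems = _parse_v41(sections, path)
    else:
        raise MeshFormatError(f"{path}: unsupported .msh version {version}")
    return _build_mesh(verts, elems, scaling_factor, path)


def _split_sections(lines, path):
    sections: dict[str, list[str]] = {}
    name = None
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("$End"):
            name = None
        elif s.startswith("$"):
            name = s[1:]
            sections[name] = []
        elif name is not None:
            sections[name].append(s)
    return sections


def _parse_v2(sections, path):
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshFormatError(f"{path}: missing $Nodes or $Elements")
    node_lines = sections["Nodes"]
    n = int(node_lines[0])
    tags = np.empty(n, dtype=np.int64)
    coords = np.empty((n, 3), dtype=np.float64)
    for i, ln in enumerate(node_lines[1 : 1 + n]):
        p = ln.split()
        tags[i] = int(p[0])
        coords[i] = [float(p[1]), float(p[2]), float(p[3])]
    elem_lines = sections["Elements"]
    m = int(elem_lines[0])
    elems = []  # (etype, label, node tag list)
    for ln in elem_lines[1 : 1 + m]:
        p = ln.split()
        etype = int(p[1])
        ntags = int(p[2])
        etags = [int(t) for t in p[3 : 3 + ntags]]
        nodes = [int(t) for t in p[3 + ntags :]]
        # prefer the physical tag (first), fall back to the entity tag
        label = 0
        if ntags >= 1 and etags[0] != 0:
            label = etags[0]
        elif ntags >= 2:
            label = etags[1]
        elems.append((etype, label, nodes))
    return (tags, coords), elems


def _parse_v41(sections, path):
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshFormatError(f"{path}: missing $Nodes or $Elements")
    # map (dim, entity tag) -> physical tag (0 if none)
    phys = {}
    if "Entities" in sections:
        ent = sections["Entities"]
        counts = [int(v) for v in ent[0].split()]
        row = 1
        for dim, cnt in enumerate(counts):
            for _ in range(cnt):
                p = ent[row].split()
                row += 1
                tag = int(p[0])
                np_at = 1 + (3 if dim == 0 else 6)
                n_phys = int(p[np_at])
                phys[(dim, tag)] = int(p[np_at + 1]) if n_phys > 0 else 0
    node_lines = sections["Nodes"]
    head = node_lines[0].split()
    n_blocks = int(head[0])
    row = 1
    tag_list, coord_list = [], []
    for _ in range(n_blocks):
        _, _, _, nb = (int(v) for v in node_lines[row].split())
        row += 1
        tag_list.extend(int(node_lines[row + i]) for i in range(nb))
        row += nb
        for i in range(nb):
            p = node_lines[row + i].split()
            coord_list.append((float(p[0]), float(p[1]), float(p[2])))
        row += nb
    tags = np.array(tag_list, dtype=np.int64)
    coords = np.array(coord_list, dtype=np.float64).reshape(-1, 3)
    elem_lines = sections["Elements"]
    n_blocks = int(elem_lines[0].split()[0])
    row = 1
    elems = []
    for _ in range(n_blocks):
        dim, etag, etype, nb = (int(v) for v in elem_lines[row].split())
        row += 1
        label = phys.get((dim, etag), 0) or etag
        for i in range(nb):
            p = [int(v) for v in elem_lines[row + i].split()]
            elems.append((etype, label, p[1:]))
        row += nb
    return (tags, coords), elems


def _build_mesh(verts, elems, scaling_factor, path):
    tags, coords = verts
    index = {int(t): i for i, t in enumerate(tags)}
    vols = [(t, lab, nd) for t, lab, nd in elems if t in (_GMSH_TET, _GMSH_HEX)]
    if not vols:
        raise UnsupportedMeshError(f"{path}: no tet4 or hex8 volume elements found")
    vol_types = {t for t, _, _ in vols}
    if len(vol_types) > 1:
        raise UnsupportedMeshError(f"{path}: mixed tet/hex volume elements not supported")
    vtype = vol_types.pop()
    element_type = TET if vtype == _GMSH_TET else HEX
    ftype = _GMSH_TRI if vtype == _GMSH_TET else _GMSH_QUAD
    cells = np.array([[index[n] for n in nd] for _, _, nd in vols], dtype=np.int64)
    facets, labels = [], []
    for t, lab, nd in elems:
        if t == ftype:
            facets.append([index[n] for n in nd])
            labels.append(lab)
    if not facets:
        raise MissingLabelsError(f"{path}: no labeled boundary facets of the matching dimension")
    mesh = LabeledMesh(
        coords * float(scaling_factor),
        cells,
        np.array(facets, dtype=np.int64),
        np.array(labels, dtype=np.int64),
        element_type,
    )
    # meshes authored with negative Jacobians are repaired by vertex swap
    vol = mesh.cell_volumes()
    if np.any(vol < 0):
        flip = vol < 0
        if element_type == TET:
            mesh.cells[flip] = mesh.cells[flip][:, [0, 2, 1, 3]]
        else:
            mesh.cells[flip] = mesh.cells[flip][:, [4, 5, 6, 7, 0, 1, 2, 3]]
    return mesh


def write_msh(mesh: LabeledMesh, path) -> None:
    """Write a LabeledMesh as Gmsh ASCII v2.2 (facets first, then cells)."""
    vtype = _GMSH_TET if mesh.element_type == TET else _GMSH_HEX
    ftype = _GMSH_TRI if mesh.element_type == TET else _GMSH_QUAD
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        total = mesh.facets.shape[0] + mesh.n_cells
        fh.write(f"$Elements\n{total}\n")
        eid = 1
        for f, lab in zip(mesh.facets, mesh.facet_labels):
            nodes = " ".join(str(v + 1) for v in f)
            fh.write(f"{eid} {ftype} 2 {lab} {lab} {nodes}\n")
            eid += 1
        for c in mesh.cells:
            nodes = " ".join(str(v + 1) for v in c)
            fh.write(f"{eid} {vtype} 2 1 1 {nodes}\n")
            eid += 1
        fh.write("$EndElements\n")


# --------------------------------------------------------------------- output


def write_fields(mesh: LabeledMesh, fields: FieldBundle, path, enabled: bool = True,
                 fmt: str | None = None) -> list:
    """Write nodal fields for visualization.

    Parameters
    ----------
    path : path-like
        Output basename; the extension selects/receives the format.
    enabled : bool
        When False nothing is written (mirrors the ``Enable output`` switch).
    fmt : {"xdmf", "vtu", None}
        None picks XDMF+HDF5 when h5py is importable, VTU otherwise.

    Returns the list of files written.
    """
    if not enabled:
        return []
    if fields.mesh is not mesh:
        for v in list(fields.scalars.values()):
            if v.shape[0] != mesh.n_vertices:
                raise MeshError("field bundle not aligned with mesh")
    if fmt is None:
        try:
            import h5py  # noqa: F401

            fmt = "xdmf"
        except ImportError:  # pragma: no cover - h5py is a hard dependency
            fmt = "vtu"
    path = os.fspath(path)
    base, ext = os.path.splitext(path)
    if ext.lower() in (".xdmf", ".vtu"):
        fmt = ext.lower()[1:]
    else:
        base = path
    if fmt == "xdmf":
        return _write_xdmf(mesh, fields, base)
    if fmt == "vtu":
        return _write_vtu(mesh, fields, base + ".vtu")
    raise ValueError(f"unknown output format {fmt!r}")


def _write_xdmf(mesh, fields, base):
    import h5py

    h5path = base + ".h5"
    xdmfpath = base + ".xdmf"
    h5name = os.path.basename(h5path)
    with h5py.File(h5path, "w") as h5:
        h5.create_dataset("mesh/vertices", data=mesh.vertices)
        h5.create_dataset("mesh/cells", data=mesh.cells)
        for name, v in fields.scalars.items():
            h5.create_dataset(f"fields/{name}", data=v)
        for name, v in fields.vectors.items():
            h5.create_dataset(f"fields/{name}", data=v)
    topo = "Tetrahedron" if mesh.element_type == TET else "Hexahedron"
    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    grid = ET.SubElement(dom, "Grid", Name="mesh", GridType="Uniform")
    topo_el = ET.SubElement(
        grid, "Topology", TopologyType=topo, NumberOfElements=str(mesh.n_cells)
    )
    _data_item(topo_el, f"{mesh.n_cells} {mesh.cells.shape[1]}", f"{h5name}:/mesh/cells", "Int")
    geom = ET.SubElement(grid, "Geometry", GeometryType="XYZ")
    _data_item(geom, f"{mesh.n_vertices} 3", f"{h5name}:/mesh/vertices", "Float")
    for name, v in fields.scalars.items():
        att = ET.SubElement(grid, "Attribute", Name=name, AttributeType="Scalar", Center="Node")
        _data_item(att, f"{mesh.n_vertices}", f"{h5name}:/fields/{name}", "Float")
    for name, v in fields.vectors.items():
        att = ET.SubElement(grid, "Attribute", Name=name, AttributeType="Vector", Center="Node")
        _data_item(att, f"{mesh.n_vertices} 3", f"{h5name}:/fields/{name}", "Float")
    ET.indent(root)
    ET.ElementTree(root).write(xdmfpath, xml_declaration=True)
    return [xdmfpath, h5path]


def _data_item(parent, dims, ref, number_type):
    item = ET.SubElement(
        parent,
        "DataItem",
        Dimensions=dims,
        Format="HDF",
        NumberType=number_type,
        Precision="8",
    )
    item.text = ref
    return item


def _write_vtu(mesh, fields, path):
    vtk_type = 10 if mesh.element_type == TET else 12
    nv_cell = mesh.cells.shape[1]

    def arr(a, fmt="%.17g"):
        return " ".join(fmt % v for v in np.asarray(a).ravel())

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        ug, "Piece", NumberOfPoints=str(mesh.n_vertices), NumberOfCells=str(mesh.n_cells)
    )
    pdata = ET.SubElement(piece, "PointData")
    for name, v in fields.scalars.items():
        da = ET.SubElement(
            pdata, "DataArray", type="Float64", Name=name, format="ascii"
        )
        da.text = arr(v)
    for name, v in fields.vectors.items():
        da = ET.SubElement(
            pdata, "DataArray", type="Float64", Name=name,
            NumberOfComponents="3", format="ascii",
        )
        da.text = arr(v)
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = arr(mesh.vertices)
    cells_el = ET.SubElement(piece, "Cells")
    da = ET.SubElement(cells_el, "DataArray", type="Int64", Name="connectivity", format="ascii")
    da.text = arr(mesh.cells, "%d")
    da = ET.SubElement(cells_el, "DataArray", type="Int64", Name="offsets", format="ascii")
    da.text = arr(np.arange(1, mesh.n_cells + 1) * nv_cell, "%d")
    da = ET.SubElement(cells_el, "DataArray", type="UInt8", Name="types", format="ascii")
    da.text = arr(np.full(mesh.n_cells, vtk_type), "%d")
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True)
    return [path]
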