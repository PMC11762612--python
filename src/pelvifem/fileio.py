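"""Mesh and table I/O: Gmsh MSH 2.2, VTU (XML ASCII), STL-in and CSV.

Minimal, dependency-free readers/writers for the ASCII flavours of the
standard formats.  Region labels travel as physical names (MSH) or cell data
plus a name map (VTU); named node patches travel as per-patch node-data
fields.  Structures the formats cannot carry (fracture face pairs, tie
pairs, metadata) are written to a ``<path>.aux.json`` sidecar and merged
back on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import FacePair, MeshError, TetMesh

SUPPORTED_FORMATS = ("msh", "vtu")


class IOError_(ValueError):
    pass


def _region_codes(mesh: TetMesh):
    names = mesh.regions()
    code = {name: i + 1 for i, name in enumerate(names)}
    return names, np.array([code[r] for r in mesh.element_region], dtype=np.int64)


def _aux_path(path) -> Path:
    return Path(str(path) + ".aux.json")


def _write_aux(mesh: TetMesh, path) -> None:
    aux = {}
    if mesh.fracture_face_pairs:
        aux["fracture_face_pairs"] = {
            name: {"medial": p.medial.tolist(), "lateral": p.lateral.tolist(),
                   "axis": p.axis.tolist(), "bridged": p.bridged.tolist()}
            for name, p in mesh.fracture_face_pairs.items()}
    if mesh.tie_pairs.size:
        aux["tie_pairs"] = mesh.tie_pairs.tolist()
    if mesh.metadata:
        aux["metadata"] = json.loads(json.dumps(mesh.metadata, default=float))
    if aux:
        _aux_path(path).write_text(json.dumps(aux, sort_keys=True))


def _read_aux(mesh: TetMesh, path) -> None:
    p = _aux_path(path)
    if not p.exists():
        return
    aux = json.loads(p.read_text())
    for name, d in aux.get("fracture_face_pairs", {}).items():
        mesh.fracture_face_pairs[name] = FacePair(
            name=name, medial=np.array(d["medial"]), lateral=np.array(d["lateral"]),
            axis=np.array(d["axis"]), bridged=np.array(d["bridged"], dtype=bool))
    if "tie_pairs" in aux:
        mesh.tie_pairs = np.array(aux["tie_pairs"], dtype=np.int64).reshape(-1, 2)
    mesh.metadata.update(aux.get("metadata", {}))


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII
# ---------------------------------------------------------------------------

def write_msh(mesh: TetMesh, path) -> None:
    """Write MSH 2.2 ASCII: regions as physical volumes, patches as NodeData."""
    names, codes = _region_codes(mesh)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(names))]
    for i, name in enumerate(names):
        lines.append(f'3 {i + 1} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_elements))
    for e, (tet, c) in enumerate(zip(mesh.tets + 1, codes), start=1):
        lines.append(f"{e} 4 2 {c} {c} " + " ".join(map(str, tet)))
    lines.append("$EndElements")
    for pname, ids in sorted(mesh.surface_patches.items()):
        flag = np.zeros(mesh.n_nodes)
        flag[np.asarray(ids)] = 1.0
        lines += ["$NodeData", "1", f'"patch:{pname}"', "1", "0.0", "3", "0", "1",
                  str(mesh.n_nodes)]
        lines += [f"{i + 1} {v:.1f}" for i, v in enumerate(flag)]
        lines.append("$EndNodeData")
    Path(path).write_text("\n".join(lines) + "\n")
    _write_aux(mesh, path)


def read_msh(path) -> TetMesh:
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag):
        out = []
        for line in it:
            if line.strip() == tag:
                return out
            out.append(line)
        raise IOError_(f"malformed MSH file: missing {tag}")

    names = {}
    nodes = tets = codes = None
    patches = {}
    for line in it:
        s = line.strip()
        if s == "$PhysicalNames":
            block = until("$EndPhysicalNames")
            for row in block[1:]:
                parts = row.split(maxsplit=2)
                names[int(parts[1])] = parts[2].strip('"')
        elif s == "$Nodes":
            block = until("$EndNodes")
            n = int(block[0])
            nodes = np.array([[float(v) for v in row.split()[1:4]]
                              for row in block[1:n + 1]])
        elif s == "$Elements":
            block = until("$EndElements")
            n = int(block[0])
            tets, codes = [], []
            for row in block[1:n + 1]:
                parts = [int(v) for v in row.split()]
                if parts[1] != 4:
                    continue
                ntags = parts[2]
                codes.append(parts[3])
                tets.append(parts[3 + ntags:7 + ntags])
            tets = np.array(tets, dtype=np.int64) - 1
            codes = np.array(codes)
        elif s == "$NodeData":
            block = until("$EndNodeData")
            name = block[1].strip('"')
            n = int(block[7])
            vals = np.array([float(r.split()[1]) for r in block[8:8 + n]])
            if name.startswith("patch:"):
                patches[name[6:]] = np.flatnonzero(vals > 0.5).astype(np.int64)
    if nodes is None or tets is None:
        raise IOError_("malformed MSH file: nodes or elements missing")
    region = np.array([names.get(c, f"region_{c}") for c in codes], dtype="<U40")
    mesh = TetMesh(nodes=nodes, tets=tets, element_region=region,
                   surface_patches=patches)
    _read_aux(mesh, path)
    return mesh


# ---------------------------------------------------------------------------
# VTU (XML ASCII, UnstructuredGrid)
# ---------------------------------------------------------------------------

def _data_array(name, data, dtype="Float64", ncomp=None) -> str:
    data = np.asarray(data)
    flat = data.reshape(data.shape[0], -1)
    ncomp = ncomp or flat.shape[1]
    if dtype.startswith("Float"):
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in flat)
    else:
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in flat)
    return (f'<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>')


def write_vtu(mesh: TetMesh, path, point_data=None, cell_data=None) -> None:
    """Write a VTU with region ids (+ name map in the aux sidecar), patch
    indicator point data, and any extra per-node / per-element fields."""
    names, codes = _region_codes(mesh)
    pd_blocks = []
    for pname, ids in sorted(mesh.surface_patches.items()):
        flag = np.zeros(mesh.n_nodes)
        flag[np.asarray(ids)] = 1.0
        pd_blocks.append(_data_array(f"patch:{pname}", flag[:, None]))
    for name, arr in (point_data or {}).items():
        pd_blocks.append(_data_array(name, np.asarray(arr)))
    cd_blocks = [_data_array("region_id", codes[:, None], dtype="Int64")]
    for name, arr in (cell_data or {}).items():
        cd_blocks.append(_data_array(name, np.asarray(arr)))

    conn = "\n".join(" ".join(map(str, t)) for t in mesh.tets)
    offs = "\n".join(str(4 * (i + 1)) for i in range(mesh.n_elements))
    types = "\n".join("10" for _ in range(mesh.n_elements))
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">
<Points>
{_data_array("Points", mesh.nodes)}
</Points>
<Cells>
{_data_array("connectivity", mesh.tets.reshape(-1, 1), dtype="Int64")}
{_data_array("offsets", np.arange(1, mesh.n_elements + 1)[:, None] * 4, dtype="Int64")}
{_data_array("types", np.full((mesh.n_elements, 1), 10), dtype="Int64")}
</Cells>
<PointData>
{chr(10).join(pd_blocks)}
</PointData>
<CellData>
{chr(10).join(cd_blocks)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(xml)
    aux = _aux_path(path)
    _write_aux(mesh, path)
    # region-code -> name map rides in the sidecar as well
    existing = json.loads(aux.read_text()) if aux.exists() else {}
    existing["region_names"] = {str(i + 1): n for i, n in enumerate(names)}
    aux.write_text(json.dumps(existing, sort_keys=True))
    _ = conn, offs, types


def read_vtu(path):
    """Read back a VTU written by :func:`write_vtu`.

    Returns ``(mesh, point_data, cell_data)`` with patch/region structures
    restored.
    """
    import xml.etree.ElementTree as ET
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        txt = da.text.strip()
        ncomp = int(da.get("NumberOfComponents", "1"))
        flat = np.array([float(v) for v in txt.split()])
        return flat.reshape(-1, ncomp)

    arrays = {}
    for parent_tag in ("Points", "Cells", "PointData", "CellData"):
        parent = piece.find(parent_tag)
        if parent is None:
            continue
        for da in parent.findall("DataArray"):
            arrays[(parent_tag, da.get("Name"))] = parse(da)

    nodes = arrays[("Points", "Points")]
    tets = arrays[("Cells", "connectivity")].astype(np.int64).reshape(-1, 4)
    codes = arrays[("CellData", "region_id")].astype(int).ravel()
    aux = _aux_path(path)
    name_map = {}
    if aux.exists():
        name_map = {int(k): v for k, v in
                    json.loads(aux.read_text()).get("region_names", {}).items()}
    region = np.array([name_map.get(c, f"region_{c}") for c in codes], dtype="<U40")
    patches, point_data, cell_data = {}, {}, {}
    for (tag, name), arr in arrays.items():
        if tag == "PointData":
            if name.startswith("patch:"):
                patches[name[6:]] = np.flatnonzero(arr.ravel() > 0.5).astype(np.int64)
            else:
                point_data[name] = arr
        elif tag == "CellData" and name != "region_id":
            cell_data[name] = arr
    mesh = TetMesh(nodes=nodes, tets=tets, element_region=region,
                   surface_patches=patches)
    _read_aux(mesh, path)
    return mesh, point_data, cell_data


def write_mesh(mesh: TetMesh, path, fmt: str | None = None) -> None:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "msh":
        write_msh(mesh, path)
    elif fmt == "vtu":
        write_vtu(mesh, path)
    else:
        raise IOError_(f"unsupported format '{fmt}'; supported: {SUPPORTED_FORMATS}")


def read_mesh(path, fmt: str | None = None) -> TetMesh:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "msh":
        return read_msh(path)
    if fmt == "vtu":
        return read_vtu(path)[0]
    raise IOError_(f"unsupported format '{fmt}'; supported: {SUPPORTED_FORMATS}")


# ---------------------------------------------------------------------------
# STL surface import
# ---------------------------------------------------------------------------

def read_stl_surface(path):
    """Read an ASCII STL surface; returns (vertices, faces).

    Vertices are merged exactly; degenerate (zero-area) triangles are
    rejected with a count of offenders.
    """
    verts, faces, tri = [], [], []
    index = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "vertex":
            xyz = tuple(float(v) for v in parts[1:4])
            if xyz not in index:
                index[xyz] = len(verts)
                verts.append(xyz)
            tri.append(index[xyz])
        elif parts[0] == "endfacet":
            if len(tri) != 3:
                raise IOError_("malformed STL facet")
            faces.append(tuple(tri))
            tri = []
    if not faces:
        raise IOError_("no facets found; binary STL is not supported")
    verts = np.array(verts)
    faces = np.array(faces, dtype=np.int64)
    e1 = verts[faces[:, 1]] - verts[faces[:, 0]]
    e2 = verts[faces[:, 2]] - verts[faces[:, 0]]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    bad = int((area2 < 1e-12).sum())
    if bad:
        raise IOError_(f"STL contains {bad} degenerate triangles")
    return verts, faces


# ---------------------------------------------------------------------------
# HU and material tables
# ---------------------------------------------------------------------------

def write_hu_csv(hu: np.ndarray, path) -> None:
    pd.DataFrame({"element_id": np.arange(len(hu)), "HU": hu}).to_csv(
        path, index=False, float_format="%.6f")


def read_hu_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"element_id", "HU"} <= set(df.columns):
        raise IOError_("HU table needs columns element_id, HU")
    return df.sort_values("element_id")["HU"].to_numpy(dtype=float)


def write_material_csv(mesh: TetMesh, materials, path) -> None:
    pd.DataFrame({
        "element_id": np.arange(mesh.n_elements),
        "region": mesh.element_region,
        "HU": materials.hu, "rho_app": materials.rho_app,
        "E": materials.E, "bin_id": materials.bin_id,
    }).to_csv(path, index=False, float_format="%.6f")
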