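"""Mesh and field serialization.

Two plain-text formats are supported:

* Gmsh MSH 4.1 (ASCII) — canonical head-model format.  Tissue labels are
  stored as physical volume groups, one entity block per tissue.  A JSON
  sidecar (``<stem>.meta.json``) carries fiducials, target, affected side,
  conductivities and layer radii, which MSH has no slot for.
* Legacy VTK unstructured grid (ASCII) — field export: potentials as
  point data, element fields / tissue ids as cell data.

Readers and writers are deliberately minimal: they parse exactly the
subset they emit (plus tolerant whitespace), raising FormatError on
anything else.  Coordinates are written with 17 significant digits, so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .head_model import HeadModel, TetMesh, TISSUES

_COORD_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1
# ---------------------------------------------------------------------------

def write_msh(path, mesh: TetMesh) -> None:
    path = Path(path)
    labels_present = [t for t in TISSUES
                      if (mesh.tissue_label == t).any()]
    with path.open("w") as fh:
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n%d\n" % len(labels_present))
        for k, name in enumerate(labels_present, start=1):
            fh.write('3 %d "%s"\n' % (k, name))
        fh.write("$EndPhysicalNames\n")
        fh.write("$Entities\n0 0 0 %d\n" % len(labels_present))
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        for k in range(1, len(labels_present) + 1):
            fh.write("%d %.17g %.17g %.17g %.17g %.17g %.17g 1 %d\n"
                     % (k, *lo, *hi, k))
        fh.write("$EndEntities\n")
        n = mesh.n_nodes
        fh.write("$Nodes\n1 %d 1 %d\n" % (n, n))
        fh.write("3 1 0 %d\n" % n)
        fh.write("".join("%d\n" % (i + 1) for i in range(n)))
        fh.write("".join(
            (_COORD_FMT + " " + _COORD_FMT + " " + _COORD_FMT + "\n") % tuple(p)
            for p in mesh.nodes))
        fh.write("$EndNodes\n")
        fh.write("$Elements\n%d %d 1 %d\n"
                 % (len(labels_present), mesh.n_tets, mesh.n_tets))
        eid = 1
        for k, name in enumerate(labels_present, start=1):
            idx = np.flatnonzero(mesh.tissue_label == name)
            fh.write("3 %d 4 %d\n" % (k, len(idx)))
            for t in mesh.tets[idx]:
                fh.write("%d %d %d %d %d\n"
                         % (eid, t[0] + 1, t[1] + 1, t[2] + 1, t[3] + 1))
                eid += 1
        fh.write("$EndElements\n")


def read_msh(path) -> TetMesh:
    path = Path(path)
    try:
        text = path.read_text()
        sections = _split_sections(text)
        phys = {}
        if "PhysicalNames" in sections:
            lines = sections["PhysicalNames"]
            for line in lines[1:]:
                dim, tag, name = line.split(maxsplit=2)
                phys[int(tag)] = name.strip().strip('"')
        node_lines = sections["Nodes"]
        header = node_lines[0].split()
        n_nodes = int(header[1])
        blk = node_lines[1].split()
        n_in_block = int(blk[3])
        if n_in_block != n_nodes:
            raise FormatError("multi-block Nodes sections are not supported")
        coords = node_lines[2 + n_nodes: 2 + 2 * n_nodes]
        nodes = np.array([[float(v) for v in ln.split()] for ln in coords])
        elem_lines = sections["Elements"]
        n_blocks = int(elem_lines[0].split()[0])
        tets = []
        labels = []
        i = 1
        for _ in range(n_blocks):
            _, etag, etype, count = (int(v) for v in elem_lines[i].split())
            if etype != 4:
                raise FormatError(f"unsupported element type {etype}")
            name = phys.get(etag, "white")
            for ln in elem_lines[i + 1: i + 1 + count]:
                vals = ln.split()
                tets.append([int(v) - 1 for v in vals[1:5]])
                labels.append(name)
            i += 1 + count
        return TetMesh(nodes, np.asarray(tets, dtype=np.int64),
                       np.asarray(labels, dtype="<U11"))
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot parse MSH file {path}: {exc}") from exc


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    cur = None
    buf: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("$End"):
            sections[cur] = buf
            cur, buf = None, []
        elif line.startswith("$"):
            cur = line[1:]
        elif cur is not None:
            buf.append(line)
    if cur is not None:
        raise FormatError(f"unterminated section ${cur}")
    return sections


# ---------------------------------------------------------------------------
# legacy VTK unstructured grid
# ---------------------------------------------------------------------------

def write_vtk(path, mesh: TetMesh, point_data: dict | None = None,
              cell_data: dict | None = None, comment: str = "tdcsfem") -> None:
    """ASCII legacy VTK: tets + tissue ids, optional point/cell arrays."""
    path = Path(path)
    tissue_id = {t: i for i, t in enumerate(TISSUES)}
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n%s\nASCII\n" % comment)
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write("POINTS %d double\n" % mesh.n_nodes)
        for p in mesh.nodes:
            fh.write((_COORD_FMT + " " + _COORD_FMT + " " + _COORD_FMT + "\n")
                     % tuple(p))
        fh.write("CELLS %d %d\n" % (mesh.n_tets, 5 * mesh.n_tets))
        for t in mesh.tets:
            fh.write("4 %d %d %d %d\n" % tuple(t))
        fh.write("CELL_TYPES %d\n" % mesh.n_tets)
        fh.write("10\n" * mesh.n_tets)
        cd = {"tissue": np.array([tissue_id[str(t)]
                                  for t in mesh.tissue_label], float)}
        cd.update(cell_data or {})
        fh.write("CELL_DATA %d\n" % mesh.n_tets)
        for name, arr in cd.items():
            _write_vtk_array(fh, name, np.asarray(arr, float))
        if point_data:
            fh.write("POINT_DATA %d\n" % mesh.n_nodes)
            for name, arr in point_data.items():
                _write_vtk_array(fh, name, np.asarray(arr, float))


def _write_vtk_array(fh, name, arr):
    if arr.ndim == 1:
        fh.write("SCALARS %s double 1\nLOOKUP_TABLE default\n" % name)
        fh.write("".join((_COORD_FMT + "\n") % v for v in arr))
    elif arr.ndim == 2 and arr.shape[1] == 3:
        fh.write("VECTORS %s double\n" % name)
        fh.write("".join(
            (_COORD_FMT + " " + _COORD_FMT + " " + _COORD_FMT + "\n")
            % tuple(v) for v in arr))
    else:
        raise FormatError(f"unsupported VTK array shape {arr.shape}")


def read_vtk(path) -> tuple[TetMesh, dict, dict]:
    """Read back a file written by :func:`write_vtk`."""
    path = Path(path)
    try:
        tok = path.read_text().splitlines()
        i = 0

        def until(prefix):
            nonlocal i
            while not tok[i].startswith(prefix):
                i += 1
            return tok[i]

        n_pts = int(until("POINTS").split()[1])
        nodes = np.array([[float(v) for v in tok[i + 1 + k].split()]
                          for k in range(n_pts)])
        i += n_pts
        n_cells = int(until("CELLS").split()[1])
        tets = np.array([[int(v) for v in tok[i + 1 + k].split()[1:]]
                         for k in range(n_cells)], dtype=np.int64)
        i += n_cells
        point_data: dict = {}
        cell_data: dict = {}
        labels = None
        mode, count = None, 0
        i += 1
        while i < len(tok):
            line = tok[i].split()
            if not line:
                i += 1
                continue
            kw = line[0]
            if kw == "CELL_DATA":
                mode, count = cell_data, int(line[1])
            elif kw == "POINT_DATA":
                mode, count = point_data, int(line[1])
            elif kw == "SCALARS":
                name = line[1]
                i += 1  # LOOKUP_TABLE
                arr = np.array([float(tok[i + 1 + k]) for k in range(count)])
                i += count
                mode[name] = arr
            elif kw == "VECTORS":
                name = line[1]
                arr = np.array([[float(v) for v in tok[i + 1 + k].split()]
                                for k in range(count)])
                i += count
                mode[name] = arr
            i += 1
        tissue = cell_data.pop("tissue", None)
        if tissue is not None:
            labels = np.asarray(TISSUES, dtype="<U11")[
                tissue.astype(int)]
        else:
            labels = np.full(n_cells, "white", dtype="<U11")
        return TetMesh(nodes, tets, labels), point_data, cell_data
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse VTK file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# head-model round trip
# ---------------------------------------------------------------------------

def write_head(path, head: HeadModel) -> None:
    path = Path(path)
    if path.suffix != ".msh":
        raise FormatError(f"unsupported head-model extension {path.suffix!r}")
    write_msh(path, head.mesh)
    meta = {
        "coordinate_convention": "RAS, millimetres, origin at sphere centre",
        "fiducials": {k: list(map(float, v))
                      for k, v in head.fiducials.items()},
        "target": list(map(float, head.target)),
        "affected_side": head.affected_side,
        "conductivities": head.conductivities,
        "layer_radii": list(head.layer_radii),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_head(path) -> HeadModel:
    path = Path(path)
    if path.suffix != ".msh":
        raise FormatError(f"unsupported head-model extension {path.suffix!r}")
    mesh = read_msh(path)
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    return HeadModel(
        mesh=mesh,
        conductivities=dict(meta["conductivities"]),
        fiducials={k: np.asarray(v, float)
                   for k, v in meta["fiducials"].items()},
        target=np.asarray(meta["target"], float),
        affected_side=meta["affected_side"],
        layer_radii=tuple(meta["layer_radii"]),
    )


def mesh_io_roundtrip(head: HeadModel, path) -> HeadModel:
    """Write then re-read a head model, verifying exact reproduction."""
    write_head(path, head)
    back = read_head(path)
    if not np.array_equal(back.mesh.nodes, head.mesh.nodes):
        raise FormatError("round trip changed node coordinates")
    # element order is regrouped by tissue; compare as sets of labeled tets
    a = _canonical(head.mesh)
    b = _canonical(back.mesh)
    if not (a == b).all():
        raise FormatError("round trip changed connectivity or labels")
    return back


def _canonical(mesh: TetMesh):
    rec = np.concatenate(
        [mesh.tets, np.array([[TISSUES.index(str(t))]
                              for t in mesh.tissue_label])], axis=1)
    return rec[np.lexsort(rec.T[::-1])]
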