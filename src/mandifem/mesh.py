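"""Labeled tetrahedral meshes: data model, VTK/Abaqus-INP I/O, TET4->TET10
promotion, geometric quantities and validation.

A :class:`LabeledMesh` is a volumetric tetrahedral mesh in which every element
carries exactly one anatomical region label (masticatory margin ``MM``, blade
``BLADE``, dorsal articulation ``DMA``, ventral articulation ``VMA``) and named
node sets mark the surface patches where biting boundary conditions act
(tooth tips, articulation patches, apodeme insertion).

Conventions
-----------
* Node and element ids are 0-based internally.  Both file dialects use 1-based
  ids; the conversion happens at the I/O boundary and nowhere else.
* Coordinates are micrometres.  With forces in micronewtons this makes
  stresses come out in MPa (1 uN / um^2 = 1 MPa).
* TET10 node ordering: 4 corner nodes first, then mid-edge nodes on edges
  (0,1), (1,2), (2,0), (0,3), (1,3), (2,3).  This is the ordering shared by
  VTK ``VTK_QUADRATIC_TETRA`` and Abaqus ``C3D10``, so no permutation is
  needed on I/O for either dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGIONS",
    "REGION_CODES",
    "LabeledMesh",
    "read_mesh",
    "write_mesh",
    "promote_tet4_to_tet10",
    "element_volume",
    "element_volumes",
    "validate_mesh",
    "tet_box_mesh",
    "MeshFormatError",
    "MeshLabelError",
]

#: Canonical region labels and their integer codes in VTK cell-data arrays.
REGIONS = ("MM", "BLADE", "DMA", "VMA")
REGION_CODES = {"MM": 0, "BLADE": 1, "DMA": 2, "VMA": 3}
_CODE_TO_REGION = {v: k for k, v in REGION_CODES.items()}

#: Mid-edge node order for TET10: local corner index pairs.
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))


class MeshFormatError(ValueError):
    """File does not parse in the requested mesh dialect."""


class MeshLabelError(ValueError):
    """Mesh file lacks required region labels."""


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with per-element region labels and named node sets.

    Parameters
    ----------
    node_coords : (n_nodes, 3) float array, micrometres.
    elements : (n_elements, 4 or 10) int array of node ids.
    element_region : (n_elements,) array of labels from :data:`REGIONS`.
    node_sets : mapping from set name to a sorted int array of node ids.
    cell_fields : optional per-element scalar arrays (e.g. ``von_mises``)
        attached for export; not part of the geometric identity.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    cell_fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_region = np.asarray(self.element_region, dtype=object)
        self.node_sets = {
            k: np.unique(np.asarray(v, dtype=np.int64)) for k, v in self.node_sets.items()
        }

    @property
    def n_nodes(self) -> int:
        return int(self.node_coords.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    @property
    def nodes_per_element(self) -> int:
        return int(self.elements.shape[1])

    @property
    def is_tet10(self) -> bool:
        return self.nodes_per_element == 10

    def corner_coords(self) -> np.ndarray:
        """(n_elements, 4, 3) corner coordinates (first 4 nodes of each tet)."""
        return self.node_coords[self.elements[:, :4]]

    def region_mask(self, region: str) -> np.ndarray:
        return self.element_region == region

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.node_coords.copy(),
            self.elements.copy(),
            self.element_region.copy(),
            {k: v.copy() for k, v in self.node_sets.items()},
            {k: np.asarray(v).copy() for k, v in self.cell_fields.items()},
        )


# ---------------------------------------------------------------------------
# geometry


def _corner_volumes_signed(mesh: LabeledMesh) -> np.ndarray:
    c = mesh.corner_coords()
    e1 = c[:, 1] - c[:, 0]
    e2 = c[:, 2] - c[:, 0]
    e3 = c[:, 3] - c[:, 0]
    return np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0


def element_volumes(mesh: LabeledMesh) -> np.ndarray:
    """Volumes (um^3) of all elements.

    For straight-edged TET10 the isoparametric volume equals the corner
    tetrahedron volume, so the determinant closed form is used for both
    element types.
    """
    return np.abs(_corner_volumes_signed(mesh))


def element_volume(mesh: LabeledMesh, element_id: int) -> float:
    """Volume (um^3) of one element; raises on degenerate geometry."""
    all_v = element_volumes(mesh)
    v = float(all_v[element_id])
    if v <= 0 or v < 1e-12 * float(np.mean(all_v)):
        raise ValueError(f"element {element_id} is degenerate (volume {v:g})")
    return v


# ---------------------------------------------------------------------------
# validation


def validate_mesh(mesh: LabeledMesh) -> list[str]:
    """Check the mesh invariants; return a list of violations (empty = valid)."""
    report: list[str] = []
    n, npe = mesh.n_nodes, mesh.nodes_per_element
    if npe not in (4, 10):
        report.append(f"unsupported nodes-per-element {npe} (expected 4 or 10)")
        return report
    if mesh.elements.size and (mesh.elements.min() < 0 or mesh.elements.max() >= n):
        report.append("element references a non-existent node id")
    for eid, elem in enumerate(mesh.elements):
        if len(set(elem.tolist())) != npe:
            report.append(f"element {eid} repeats a node id")
    if mesh.element_region.shape[0] != mesh.n_elements:
        report.append("element_region length does not match element count")
    else:
        bad = set(mesh.element_region) - set(REGIONS)
        if bad:
            report.append(f"unknown region labels: {sorted(map(str, bad))}")
    signed = _corner_volumes_signed(mesh)
    n_neg = int(np.sum(signed <= 0))
    if n_neg:
        report.append(f"negative Jacobian (inverted or flat) in {n_neg} element(s)")
    vols = np.abs(signed)
    if vols.size:
        tiny = vols < 1e-12 * float(vols.mean())
        n_tiny = int(np.sum(tiny & (signed > 0)))
        if n_tiny:
            report.append(f"degenerate element volume in {n_tiny} element(s)")
    for name, ids in mesh.node_sets.items():
        if ids.size and (ids.min() < 0 or ids.max() >= n):
            report.append(f"dangling node set '{name}' references missing nodes")
    return report


# ---------------------------------------------------------------------------
# TET4 -> TET10 promotion


def promote_tet4_to_tet10(mesh: LabeledMesh) -> LabeledMesh:
    """Insert one mid-edge node per unique edge, shared between neighbours.

    Corner coordinates, element order and region labels are preserved; new
    mid-edge nodes are appended after the existing nodes in order of first
    appearance of their edge.  A node set gains the mid-edge node of every
    edge whose two endpoints it contains, so sets marking surface patches
    keep marking the whole patch.
    """
    if mesh.nodes_per_element != 4:
        raise ValueError("promotion requires a pure TET4 mesh")
    coords = mesh.node_coords
    edge_mid: dict[tuple[int, int], int] = {}
    new_coords: list[np.ndarray] = []
    next_id = mesh.n_nodes
    elems10 = np.empty((mesh.n_elements, 10), dtype=np.int64)
    elems10[:, :4] = mesh.elements
    for eid, elem in enumerate(mesh.elements):
        for k, (a, b) in enumerate(TET10_EDGES):
            key = (int(elem[a]), int(elem[b]))
            key = (min(key), max(key))
            mid = edge_mid.get(key)
            if mid is None:
                mid = next_id
                edge_mid[key] = mid
                new_coords.append(0.5 * (coords[key[0]] + coords[key[1]]))
                next_id += 1
            elems10[eid, 4 + k] = mid
    all_coords = np.vstack([coords, np.array(new_coords)]) if new_coords else coords.copy()
    node_sets = {}
    for name, ids in mesh.node_sets.items():
        members = set(ids.tolist())
        extra = [mid for (a, b), mid in edge_mid.items() if a in members and b in members]
        node_sets[name] = np.array(sorted(members | set(extra)), dtype=np.int64)
    return LabeledMesh(all_coords, elems10, mesh.element_region.copy(), node_sets)


# ---------------------------------------------------------------------------
# VTK legacy unstructured-grid dialect

_VTK_TETRA = 10
_VTK_QUADRATIC_TETRA = 24


def _write_vtk(mesh: LabeledMesh, fh: io.TextIOBase) -> None:
    npe = mesh.nodes_per_element
    ctype = _VTK_TETRA if npe == 4 else _VTK_QUADRATIC_TETRA
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write("mandifem labeled tetrahedral mesh (units: micrometres)\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    fh.write(f"POINTS {mesh.n_nodes} double\n")
    for p in mesh.node_coords:
        fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (npe + 1)}\n")
    for elem in mesh.elements:
        fh.write(str(npe) + " " + " ".join(map(str, elem.tolist())) + "\n")
    fh.write(f"CELL_TYPES {mesh.n_elements}\n")
    fh.write("".join(f"{ctype}\n" for _ in range(mesh.n_elements)))
    fh.write(f"CELL_DATA {mesh.n_elements}\n")
    fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
    fh.write("".join(f"{REGION_CODES[r]}\n" for r in mesh.element_region))
    for name, values in mesh.cell_fields.items():
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        fh.write("".join(f"{float(v):.17g}\n" for v in np.asarray(values)))
    if mesh.node_sets:
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, ids in mesh.node_sets.items():
            flags = np.zeros(mesh.n_nodes, dtype=int)
            flags[ids] = 1
            fh.write(f"SCALARS nset:{name} int 1\nLOOKUP_TABLE default\n")
            fh.write("".join(f"{f}\n" for f in flags))


def _read_vtk(text: str) -> LabeledMesh:
    tokens = []
    for line in text.splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            tokens.extend(s.split())
    pos = 0

    def peek() -> str:
        return tokens[pos] if pos < len(tokens) else ""

    def take(n: int = 1) -> list[str]:
        nonlocal pos
        out = tokens[pos : pos + n]
        pos += n
        return out

    coords = elements = None
    region_codes = None
    cell_fields: dict[str, np.ndarray] = {}
    point_flags: dict[str, np.ndarray] = {}
    n_points = n_cells = 0
    section = None  # "cell" or "point"
    try:
        while pos < len(tokens):
            tok = peek().upper()
            if tok == "POINTS":
                take(1)
                n_points = int(take(1)[0])
                take(1)  # dtype
                vals = np.array(take(3 * n_points), dtype=float)
                coords = vals.reshape(n_points, 3)
            elif tok == "CELLS":
                take(1)
                n_cells = int(take(1)[0])
                total = int(take(1)[0])
                raw = np.array(take(total), dtype=np.int64)
                elems, i = [], 0
                for _ in range(n_cells):
                    cnt = int(raw[i])
                    elems.append(raw[i + 1 : i + 1 + cnt])
                    i += 1 + cnt
                sizes = {len(e) for e in elems}
                if sizes - {4, 10}:
                    raise MeshFormatError(f"non-tetrahedral cell sizes {sorted(sizes)}")
                if len(sizes) > 1:
                    raise MeshFormatError("mixed TET4/TET10 meshes are not supported")
                elements = np.array(elems, dtype=np.int64)
            elif tok == "CELL_TYPES":
                take(1)
                n = int(take(1)[0])
                types = set(map(int, take(n)))
                if types - {_VTK_TETRA, _VTK_QUADRATIC_TETRA}:
                    raise MeshFormatError(f"unsupported VTK cell types {sorted(types)}")
            elif tok == "CELL_DATA":
                take(2)
                section = "cell"
            elif tok == "POINT_DATA":
                take(2)
                section = "point"
            elif tok == "SCALARS":
                take(1)
                name = take(1)[0]
                take(1)  # dtype
                if peek() not in ("", "LOOKUP_TABLE") and peek().isdigit():
                    take(1)  # optional component count
                if peek().upper() == "LOOKUP_TABLE":
                    take(2)
                n = n_cells if section == "cell" else n_points
                vals = np.array(take(n), dtype=float)
                if section == "cell":
                    if name == "region":
                        region_codes = vals.astype(int)
                    else:
                        cell_fields[name] = vals
                elif name.startswith("nset:"):
                    point_flags[name[5:]] = vals.astype(int)
            else:
                take(1)
    except (IndexError, ValueError) as exc:
        if isinstance(exc, MeshFormatError):
            raise
        raise MeshFormatError(f"malformed VTK legacy file: {exc}") from exc
    if coords is None or elements is None:
        raise MeshFormatError("VTK file lacks POINTS or CELLS sections")
    if region_codes is None:
        raise MeshLabelError("VTK file lacks the 'region' cell-data array")
    unknown = set(region_codes.tolist()) - set(_CODE_TO_REGION)
    if unknown:
        raise MeshLabelError(f"unknown region codes {sorted(unknown)}")
    regions = np.array([_CODE_TO_REGION[c] for c in region_codes], dtype=object)
    node_sets = {name: np.flatnonzero(flags) for name, flags in point_flags.items()}
    return LabeledMesh(coords, elements, regions, node_sets, cell_fields)


# ---------------------------------------------------------------------------
# Abaqus INP dialect (subset: *NODE, *ELEMENT C3D4/C3D10, *ELSET, *NSET)


def _write_inp(mesh: LabeledMesh, fh: io.TextIOBase) -> None:
    npe = mesh.nodes_per_element
    etype = "C3D4" if npe == 4 else "C3D10"
    fh.write("*HEADING\nmandifem labeled tetrahedral mesh (units: micrometres)\n")
    fh.write("*NODE\n")
    for nid, p in enumerate(mesh.node_coords, start=1):
        fh.write(f"{nid}, {p[0]:.17g}, {p[1]:.17g}, {p[2]:.17g}\n")
    fh.write(f"*ELEMENT, TYPE={etype}\n")
    for eid, elem in enumerate(mesh.elements, start=1):
        fh.write(f"{eid}, " + ", ".join(str(int(n) + 1) for n in elem) + "\n")
    for region in REGIONS:
        ids = np.flatnonzero(mesh.element_region == region) + 1
        if ids.size:
            fh.write(f"*ELSET, ELSET={region}\n")
            _write_id_lines(fh, ids)
    for name, ids in mesh.node_sets.items():
        fh.write(f"*NSET, NSET={name}\n")
        _write_id_lines(fh, ids + 1)


def _write_id_lines(fh: io.TextIOBase, ids: np.ndarray, per_line: int = 12) -> None:
    ids = list(map(str, ids.tolist()))
    for i in range(0, len(ids), per_line):
        fh.write(", ".join(ids[i : i + per_line]) + "\n")


def _read_inp(text: str) -> LabeledMesh:
    nodes: dict[int, list[float]] = {}
    elem_rows: list[tuple[int, list[int]]] = []
    elsets: dict[str, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    mode: tuple[str, ...] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            parts = [p.strip() for p in line.split(",")]
            key = parts[0].upper()
            opts = {}
            for p in parts[1:]:
                if "=" in p:
                    k, v = p.split("=", 1)
                    opts[k.strip().upper()] = v.strip()
            if key == "*NODE":
                mode = ("node",)
            elif key == "*ELEMENT":
                etype = opts.get("TYPE", "").upper()
                if etype not in ("C3D4", "C3D10"):
                    raise MeshFormatError(f"unsupported element type '{etype}'")
                elset = opts.get("ELSET")
                mode = ("element", elset)
            elif key == "*ELSET":
                name = opts.get("ELSET")
                if name is None:
                    raise MeshFormatError("*ELSET without ELSET= name")
                mode = ("elset", name)
                elsets.setdefault(name, [])
            elif key == "*NSET":
                name = opts.get("NSET")
                if name is None:
                    raise MeshFormatError("*NSET without NSET= name")
                mode = ("nset", name)
                nsets.setdefault(name, [])
            else:
                mode = None  # *HEADING etc.: skip data lines
            continue
        if mode is None:
            continue
        fields = [f for f in (s.strip() for s in line.split(",")) if f]
        try:
            if mode[0] == "node":
                nid = int(fields[0])
                nodes[nid] = [float(x) for x in fields[1:4]]
            elif mode[0] == "element":
                eid = int(fields[0])
                conn = [int(x) for x in fields[1:]]
                elem_rows.append((eid, conn))
                if mode[1] is not None:
                    elsets.setdefault(mode[1], []).append(eid)
            elif mode[0] == "elset":
                elsets[mode[1]].extend(int(x) for x in fields)
            elif mode[0] == "nset":
                nsets[mode[1]].extend(int(x) for x in fields)
        except ValueError as exc:
            raise MeshFormatError(f"malformed INP data line '{line}': {exc}") from exc
    if not nodes or not elem_rows:
        raise MeshFormatError("INP file lacks *NODE or *ELEMENT data")
    node_ids = sorted(nodes)
    id_map = {nid: i for i, nid in enumerate(node_ids)}
    coords = np.array([nodes[nid] for nid in node_ids])
    elem_rows.sort(key=lambda r: r[0])
    sizes = {len(conn) for _, conn in elem_rows}
    if len(sizes) > 1:
        raise MeshFormatError("mixed TET4/TET10 meshes are not supported")
    elements = np.array(
        [[id_map[n] for n in conn] for _, conn in elem_rows], dtype=np.int64
    )
    eid_map = {eid: i for i, (eid, _) in enumerate(elem_rows)}
    regions = np.array([None] * len(elem_rows), dtype=object)
    for name, eids in elsets.items():
        if name in REGIONS:
            for eid in eids:
                regions[eid_map[eid]] = name
    if any(r is None for r in regions):
        raise MeshLabelError("INP file leaves elements without a region ELSET")
    node_sets = {
        name: np.array(sorted(id_map[n] for n in ids), dtype=np.int64)
        for name, ids in nsets.items()
    }
    return LabeledMesh(coords, elements, regions, node_sets)


# ---------------------------------------------------------------------------
# public I/O


def write_mesh(mesh: LabeledMesh, path, format: str = "vtk") -> None:
    """Write a mesh in the ``vtk`` (legacy ASCII) or ``abaqus_inp`` dialect."""
    with open(path, "w") as fh:
        if format == "vtk":
            _write_vtk(mesh, fh)
        elif format == "abaqus_inp":
            _write_inp(mesh, fh)
        else:
            raise ValueError(f"unknown mesh format '{format}'")


def read_mesh(path, format: str | None = None) -> LabeledMesh:
    """Read a labeled tetrahedral mesh.

    ``format`` is ``vtk`` or ``abaqus_inp``; if omitted it is inferred from
    the file suffix (``.vtk`` / ``.inp``).
    """
    path = str(path)
    if format is None:
        format = "abaqus_inp" if path.lower().endswith(".inp") else "vtk"
    with open(path) as fh:
        text = fh.read()
    mesh = _read_vtk(text) if format == "vtk" else _read_inp(text)
    problems = [p for p in validate_mesh(mesh) if "degenerate" not in p]
    if problems:
        raise MeshFormatError(f"mesh failed validation on read: {problems}")
    return mesh


# ---------------------------------------------------------------------------
# structured helper meshes


def tet_box_mesh(
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
    region: str = "BLADE",
) -> LabeledMesh:
    """Structured TET4 mesh of a box, each grid cell split into 6 tetrahedra.

    Used for verification problems (bars, cantilevers, patch tests) and as the
    lattice backbone of the synthetic mandible generator.  Node sets ``xmin``
    and ``xmax`` mark the two end faces.
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    return tet_grid_mesh(xs, ys, zs, region=region)


# 6-tet decomposition of a unit cell (consistent diagonals -> conforming mesh)
_CUBE_TETS = (
    (0, 1, 3, 7),
    (0, 1, 7, 5),
    (0, 5, 7, 4),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
)


def tet_grid_mesh(xs, ys, zs, region: str = "BLADE") -> LabeledMesh:
    """Tetrahedralize the structured grid spanned by coordinate vectors."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [
                    nid(i, j, k),
                    nid(i + 1, j, k),
                    nid(i, j + 1, k),
                    nid(i + 1, j + 1, k),
                    nid(i, j, k + 1),
                    nid(i + 1, j, k + 1),
                    nid(i, j + 1, k + 1),
                    nid(i + 1, j + 1, k + 1),
                ]
                for t in _CUBE_TETS:
                    elems.append([c[t[0]], c[t[1]], c[t[2]], c[t[3]]])
    elements = np.array(elems, dtype=np.int64)
    # fix orientation: ensure positive signed volume
    c = coords[elements]
    sv = np.einsum(
        "ij,ij->i", np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]), c[:, 3] - c[:, 0]
    )
    flip = sv < 0
    elements[flip, 2], elements[flip, 3] = (
        elements[flip, 3].copy(),
        elements[flip, 2].copy(),
    )
    regions = np.array([region] * len(elements), dtype=object)
    node_sets = {
        "xmin": np.flatnonzero(np.isclose(coords[:, 0], xs[0])),
        "xmax": np.flatnonzero(np.isclose(coords[:, 0], xs[-1])),
    }
    return LabeledMesh(coords, elements, regions, node_sets)
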