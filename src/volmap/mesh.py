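"""Surface and volume meshes for the torso/heart geometry.

Coordinates are right-handed millimetres with 0-based node indexing.  The
module provides the triangulated torso and heart surfaces, the tetrahedral
volume mesh of the torso interior with a flagged myocardial shell, electrode
attachment, lumped nodal volume weights (the discrete volume measure used by
the source existence condition), and edge-graph geodesic distances.

Mesh I/O covers legacy-VTK and VTU ASCII (read/write) and OFF/STL (read,
via trimesh).  Electrode tables are CSV with columns ``id,x,y,z`` in mm.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import trimesh
from scipy.spatial import Delaunay, cKDTree

from .fem import boundary_faces, tet_volumes

__all__ = [
    "MeshValidationError",
    "TriSurfaceMesh",
    "TetVolumeMesh",
    "ElectrodeSet",
    "VolumeWeights",
    "load_mesh",
    "save_mesh",
    "read_electrodes_csv",
    "write_electrodes_csv",
    "solid_angles",
    "winding_number",
    "tetrahedralize",
    "node_volume_weights",
    "geodesic_distance",
    "geodesic_distances",
    "icosphere_surface",
    "fibonacci_directions",
    "attach_electrodes",
    "boundary_surface",
    "build_phantom_geometry",
]


class MeshValidationError(ValueError):
    """A mesh violated a structural invariant (manifoldness, orientation...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TriSurfaceMesh:
    """Closed, consistently oriented triangulated surface (mm)."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int
    role: str = "torso"  # torso | epicardium | endocardium

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)

    # -- geometry ----------------------------------------------------------
    def triangle_areas(self) -> np.ndarray:
        p0, p1, p2 = (self.vertices[self.triangles[:, i]] for i in range(3))
        return np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1) / 2.0

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    @property
    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (> 0 for outward normals)."""
        p0, p1, p2 = (self.vertices[self.triangles[:, i]] for i in range(3))
        return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)

    def edges(self) -> np.ndarray:
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
             self.triangles[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    # -- validation --------------------------------------------------------
    def validate(self) -> "TriSurfaceMesh":
        t = self.triangles
        if t.min() < 0 or t.max() >= len(self.vertices):
            raise MeshValidationError("triangle index out of range")
        areas = self.triangle_areas()
        if np.any(areas <= 1e-12):
            bad = int(np.argmin(areas))
            raise MeshValidationError(f"degenerate (zero-area) triangle {bad}")
        # directed-edge census: a closed oriented 2-manifold uses every
        # undirected edge exactly twice, once in each direction.
        de = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        owner = np.tile(np.arange(len(t)), 3)
        key = de[:, 0] * len(self.vertices) + de[:, 1]
        uniq, counts = np.unique(key, return_counts=True)
        if np.any(counts > 1):
            dup = uniq[counts > 1][0]
            tris = np.sort(owner[key == dup])
            raise MeshValidationError(
                f"inconsistent orientation: directed edge repeated in "
                f"triangles {tris.tolist()}"
            )
        rev = de[:, 1] * len(self.vertices) + de[:, 0]
        if not np.array_equal(np.sort(key), np.sort(rev)):
            raise MeshValidationError("surface is not a closed 2-manifold")
        if self.enclosed_volume <= 0:
            raise MeshValidationError(
                "surface normals are not outward (negative enclosed volume)"
            )
        return self


@dataclass
class TetVolumeMesh:
    """Tetrahedral mesh of the full torso interior with a myocardial mask."""

    vertices: np.ndarray  # (n, 3)
    tetrahedra: np.ndarray  # (k, 4)
    heart_node_mask: np.ndarray  # (n,) bool

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.tetrahedra = np.ascontiguousarray(self.tetrahedra, dtype=np.int64)
        self.heart_node_mask = np.asarray(self.heart_node_mask, dtype=bool)

    @property
    def heart_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.heart_node_mask)

    def heart_tets(self) -> np.ndarray:
        """Tets whose four nodes are all myocardial (the discrete heart volume)."""
        return self.tetrahedra[self.heart_node_mask[self.tetrahedra].all(axis=1)]

    def edge_list(self) -> np.ndarray:
        t = self.tetrahedra
        pairs = [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]
        e = np.vstack([t[:, p] for p in pairs])
        return np.unique(np.sort(e, axis=1), axis=0)

    def orient(self) -> "TetVolumeMesh":
        """Flip node order of negatively oriented tets in place."""
        vols = tet_volumes(self.vertices, self.tetrahedra)
        neg = vols < 0
        self.tetrahedra[neg] = self.tetrahedra[neg][:, [0, 1, 3, 2]]
        return self

    def validate(self) -> "TetVolumeMesh":
        vols = tet_volumes(self.vertices, self.tetrahedra)
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise MeshValidationError(f"non-positive tet volume at element {bad}")
        if self.heart_node_mask.sum() == 0:
            raise MeshValidationError("empty heart node mask")
        # heart nodes must form a connected edge subgraph
        hn = self.heart_nodes
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[hn] = np.arange(len(hn))
        e = self.edge_list()
        keep = self.heart_node_mask[e].all(axis=1)
        eh = remap[e[keep]]
        g = sp.coo_matrix(
            (np.ones(len(eh)), (eh[:, 0], eh[:, 1])), shape=(len(hn), len(hn))
        )
        ncomp, _ = csgraph.connected_components(g, directed=False)
        if ncomp != 1:
            raise MeshValidationError(
                f"heart nodes split into {ncomp} connected components"
            )
        return self


@dataclass
class ElectrodeSet:
    """Body-surface electrodes snapped to torso-mesh vertices."""

    positions: np.ndarray  # (M, 3) nominal positions, mm
    attached_vertex: np.ndarray  # (M,) vertex index on the torso boundary

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.attached_vertex = np.asarray(self.attached_vertex, dtype=np.int64)
        if len(self.positions) < 2:
            raise MeshValidationError("need at least 2 electrodes")
        if len(np.unique(self.attached_vertex)) != len(self.attached_vertex):
            raise MeshValidationError("electrode attached vertices not distinct")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class VolumeWeights:
    """Lumped nodal volumes (mm^3) over the myocardium.

    ``weights`` is full mesh length with zeros outside the heart; it is the
    discrete quadrature of the volume integral in the source existence
    condition, so ``weights @ f`` approximates the net source over the heart.
    """

    weights: np.ndarray  # (n,) mm^3, zero outside heart
    heart_nodes: np.ndarray  # (P,) indices

    @property
    def heart_weights(self) -> np.ndarray:
        return self.weights[self.heart_nodes]

    @property
    def total_volume(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _write_vtk_legacy(path, points, cells, cell_type, point_data):
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvolmap mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(points)} double\n")
        np.savetxt(f, points, fmt="%.17g")
        n, k = cells.shape
        f.write(f"CELLS {n} {n * (k + 1)}\n")
        block = np.column_stack([np.full(n, k), cells])
        np.savetxt(f, block, fmt="%d")
        f.write(f"CELL_TYPES {n}\n")
        np.savetxt(f, np.full(n, cell_type), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_data.items():
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%d" if kind == "int" else "%.17g")


def _read_vtk_legacy(path):
    tokens = Path(path).read_text().split()
    it = iter(range(len(tokens)))

    def find(word, start=0):
        for i in range(start, len(tokens)):
            if tokens[i].upper() == word:
                return i
        raise ValueError(f"{word} section missing in {path}")

    ip = find("POINTS")
    npts = int(tokens[ip + 1])
    pts = np.array(tokens[ip + 3: ip + 3 + 3 * npts], dtype=float).reshape(-1, 3)
    try:
        ic = find("CELLS")
    except ValueError:
        ic = find("POLYGONS")
    ncell = int(tokens[ic + 1])
    total = int(tokens[ic + 2])
    raw = np.array(tokens[ic + 3: ic + 3 + total], dtype=np.int64)
    k = raw[0]
    cells = raw.reshape(ncell, k + 1)[:, 1:]
    point_data = {}
    i = ic + 3 + total
    while True:
        try:
            isc = find("SCALARS", i)
        except ValueError:
            break
        name = tokens[isc + 1]
        dt = tokens[isc + 2]
        vals = np.array(
            tokens[isc + 6: isc + 6 + npts],
            dtype=np.int64 if dt == "int" else float,
        )
        point_data[name] = vals
        i = isc + 6 + npts
    return pts, cells, point_data


def _write_vtu(path, points, cells, cell_type, point_data):
    n, k = cells.shape
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(len(points)), NumberOfCells=str(n)
    )
    def da(parent, name, arr, ncomp, typ):
        el = ET.SubElement(
            parent, "DataArray", type=typ, Name=name,
            NumberOfComponents=str(ncomp), format="ascii",
        )
        buf = io.StringIO()
        np.savetxt(buf, np.atleast_2d(arr.reshape(-1)), fmt="%.17g" if typ == "Float64" else "%d")
        el.text = buf.getvalue()
    pts_el = ET.SubElement(piece, "Points")
    da(pts_el, "Points", points, 3, "Float64")
    cells_el = ET.SubElement(piece, "Cells")
    da(cells_el, "connectivity", cells, 1, "Int64")
    da(cells_el, "offsets", np.arange(1, n + 1) * k, 1, "Int64")
    da(cells_el, "types", np.full(n, cell_type), 1, "Int64")
    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            typ = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
            da(pd, name, arr, 1, typ)
    ET.ElementTree(root).write(path)


def _read_vtu(path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def arr(el, dtype):
        return np.fromstring(el.text, sep=" ", dtype=dtype)

    pts = arr(piece.find("Points/DataArray"), float).reshape(-1, 3)
    cells_el = {e.get("Name"): e for e in piece.findall("Cells/DataArray")}
    conn = arr(cells_el["connectivity"], np.int64)
    offs = arr(cells_el["offsets"], np.int64)
    k = offs[0]
    cells = conn.reshape(len(offs), k)
    point_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        for e in pd.findall("DataArray"):
            dt = np.int64 if e.get("type", "").startswith("Int") else float
            point_data[e.get("Name")] = arr(e, dt)
    return pts, cells, point_data


def save_mesh(mesh, path):
    """Write a surface or volume mesh to legacy .vtk or .vtu (ASCII)."""
    path = Path(path)
    if isinstance(mesh, TriSurfaceMesh):
        cells, ctype, pd = mesh.triangles, 5, {}
    else:
        cells, ctype = mesh.tetrahedra, 10
        pd = {"heart_mask": mesh.heart_node_mask.astype(np.int64)}
    writer = {".vtk": _write_vtk_legacy, ".vtu": _write_vtu}.get(path.suffix)
    if writer is None:
        raise ValueError(f"unsupported mesh format {path.suffix}")
    writer(path, mesh.vertices, cells, ctype, pd)


def load_mesh(path, role="torso"):
    """Load and validate a mesh; surfaces from VTK/VTU/OFF/STL, volumes from VTK/VTU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".off", ".stl"):
        tm = trimesh.load_mesh(str(path), process=(suffix == ".stl"))
        return TriSurfaceMesh(
            np.asarray(tm.vertices), np.asarray(tm.faces), role
        ).validate()
    if suffix in (".vtk", ".vtu"):
        reader = _read_vtk_legacy if suffix == ".vtk" else _read_vtu
        pts, cells, pd = reader(path)
        if cells.shape[1] == 3:
            return TriSurfaceMesh(pts, cells, role).validate()
        if cells.shape[1] == 4:
            mask = pd.get("heart_mask")
            if mask is None:
                mask = np.ones(len(pts), dtype=bool)
            return TetVolumeMesh(pts, cells, mask.astype(bool)).orient().validate()
        raise MeshValidationError(f"unsupported cell arity {cells.shape[1]}")
    raise ValueError(f"unsupported mesh format {suffix}")


def read_electrodes_csv(path):
    """Electrode table: header ``id,x,y,z``, coordinates in mm."""
    rows = Path(path).read_text().strip().splitlines()
    header = [h.strip().lower() for h in rows[0].split(",")]
    if header[:4] != ["id", "x", "y", "z"]:
        raise ValueError("electrode CSV must have header id,x,y,z")
    vals = np.array([r.split(",")[1:4] for r in rows[1:]], dtype=float)
    return vals


def write_electrodes_csv(path, electrodes: ElectrodeSet):
    lines = ["id,x,y,z"]
    for i, p in enumerate(electrodes.positions):
        lines.append(f"{i},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# point-in-surface tests (generalized winding number)
# ---------------------------------------------------------------------------

def solid_angles(tri_pts: np.ndarray, obs: np.ndarray, chunk: int = 4_000_000):
    """Signed solid angles of triangles seen from observation points.

    ``tri_pts``: (m, 3, 3) triangle vertex coordinates; ``obs``: (n, 3).
    Returns (n, m).  Uses the van Oosterom-Strackee formula; positive when
    the triangle's oriented normal faces away from the observer.
    """
    obs = np.atleast_2d(obs)
    m, n = len(tri_pts), len(obs)
    out = np.empty((n, m))
    rows = max(1, chunk // max(m, 1))
    for s in range(0, n, rows):
        o = obs[s:s + rows]
        r = tri_pts[None, :, :, :] - o[:, None, None, :]  # (b, m, 3, 3)
        nr = np.linalg.norm(r, axis=3)  # (b, m, 3)
        r0, r1, r2 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        num = np.einsum("bmi,bmi->bm", r0, np.cross(r1, r2))
        den = (
            nr.prod(axis=2)
            + np.einsum("bmi,bmi->bm", r0, r1) * nr[:, :, 2]
            + np.einsum("bmi,bmi->bm", r0, r2) * nr[:, :, 1]
            + np.einsum("bmi,bmi->bm", r1, r2) * nr[:, :, 0]
        )
        out[s:s + rows] = 2.0 * np.arctan2(num, den)
    return out


def winding_number(surface: TriSurfaceMesh, points: np.ndarray) -> np.ndarray:
    """~1 inside the closed surface, ~0 outside."""
    tri_pts = surface.vertices[surface.triangles]
    return solid_angles(tri_pts, points).sum(axis=1) / (4.0 * np.pi)


# ---------------------------------------------------------------------------
# tetrahedralization
# ---------------------------------------------------------------------------

def _bcc_lattice(bounds_lo, bounds_hi, spacing):
    axes = [np.arange(lo, hi + spacing, spacing)
            for lo, hi in zip(bounds_lo, bounds_hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = grid + spacing / 2.0
    return np.vstack([grid, centers])


def tetrahedralize(
    torso: TriSurfaceMesh,
    heart_outer: TriSurfaceMesh,
    heart_inner: TriSurfaceMesh | None,
    target_edge_mm: float,
) -> TetVolumeMesh:
    """Tetrahedralize the torso interior with the myocardial shell flagged.

    Delaunay-based: input surface vertices are combined with a body-centred
    cubic filler lattice at the target spacing and tetrahedralized; elements
    whose centroid falls outside the torso are discarded.  Intended for the
    star-shaped phantom domains this package generates (a constrained
    quality mesher is out of scope); interior surfaces are honoured through
    their vertices rather than constrained facets.
    """
    torso.validate()
    heart_outer.validate()
    surfaces = [torso, heart_outer]
    if heart_inner is not None:
        heart_inner.validate()
        surfaces.append(heart_inner)
    # containment / non-intersection checks
    wn = winding_number(torso, heart_outer.vertices)
    if not np.all(wn > 0.5):
        raise MeshValidationError("heart surface not strictly inside torso")
    if heart_inner is not None:
        wn_i = winding_number(heart_outer, heart_inner.vertices)
        if not np.all(wn_i > 0.5):
            raise MeshValidationError("inner heart surface not inside outer")

    spacing = 1.09 * target_edge_mm  # BCC spacing giving ~target mean edge
    lo = torso.vertices.min(axis=0)
    hi = torso.vertices.max(axis=0)
    filler = _bcc_lattice(lo, hi, spacing)
    inside = winding_number(torso, filler) > 0.5
    filler = filler[inside]
    surf_pts = np.vstack([s.vertices for s in surfaces])
    tree = cKDTree(surf_pts)
    d, _ = tree.query(filler)
    filler = filler[d > 0.6 * target_edge_mm]

    points = np.vstack([surf_pts, filler])
    delau = Delaunay(points)
    tets = delau.simplices
    cent = points[tets].mean(axis=1)
    keep = winding_number(torso, cent) > 0.5
    tets = tets[keep]
    vols = np.abs(tet_volumes(points, tets))
    tets = tets[vols > 1e-7 * np.median(vols)]

    mask = winding_number(heart_outer, points) > 0.5
    if heart_inner is not None:
        mask &= ~(winding_number(heart_inner, points) > 0.5)
    # vertices of the heart surfaces are myocardial by construction
    n_out = len(heart_outer.vertices)
    off = len(torso.vertices)
    mask[off: off + n_out] = True
    if heart_inner is not None:
        mask[off + n_out: off + n_out + len(heart_inner.vertices)] = True
    mask[: len(torso.vertices)] = False

    mesh = TetVolumeMesh(points, tets, mask).orient()
    return mesh.validate()


def node_volume_weights(mesh: TetVolumeMesh) -> VolumeWeights:
    """Lumped weights: each myocardial tet spreads volume/4 onto its nodes."""
    ht = mesh.heart_tets()
    if len(ht) == 0:
        raise MeshValidationError("no fully myocardial tetrahedra")
    vols = tet_volumes(mesh.vertices, ht)
    w = np.zeros(len(mesh.vertices))
    np.add.at(w, ht.reshape(-1), np.repeat(vols / 4.0, 4))
    hn = mesh.heart_nodes
    if np.any(w[hn] <= 0):
        raise MeshValidationError(
            "heart node without adjacent myocardial tet (weight 0)"
        )
    return VolumeWeights(w, hn)


# ---------------------------------------------------------------------------
# geodesics (edge-graph shortest paths)
# ---------------------------------------------------------------------------

def _edge_graph(mesh, subset_mask=None) -> sp.csr_matrix:
    if isinstance(mesh, TriSurfaceMesh):
        e = mesh.edges()
    else:
        e = mesh.edge_list()
    if subset_mask is not None:
        e = e[subset_mask[e].all(axis=1)]
    n = len(mesh.vertices)
    lens = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    g = sp.coo_matrix((lens, (e[:, 0], e[:, 1])), shape=(n, n))
    return (g + g.T).tocsr()


def geodesic_distances(mesh, source: int, subset_mask=None) -> np.ndarray:
    """Dijkstra distances (mm) from one node to all nodes over the edge graph."""
    g = _edge_graph(mesh, subset_mask)
    return csgraph.dijkstra(g, directed=False, indices=source)


def geodesic_distance(mesh, node_a: int, node_b: int, subset_mask=None) -> float:
    """Edge-graph geodesic between two nodes; inf if disconnected."""
    if node_a == node_b:
        return 0.0
    return float(geodesic_distances(mesh, node_a, subset_mask)[node_b])


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (golden-spiral lattice), deterministic."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def icosphere_surface(radius, target_edge_mm, center=(0, 0, 0), role="torso"):
    """Icosphere surface whose edge length approximates the target."""
    # subdiv-2 icosphere has mean edge ~0.299 R; each level halves it
    sub = int(np.clip(round(2 + np.log2(0.299 * radius / target_edge_mm)), 1, 6))
    tm = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return TriSurfaceMesh(
        np.asarray(tm.vertices) + np.asarray(center, dtype=float),
        np.asarray(tm.faces),
        role,
    ).validate()


def attach_electrodes(positions, surface_vertices, candidate_idx=None):
    """Snap electrode positions to distinct nearest vertices (greedy)."""
    if candidate_idx is None:
        candidate_idx = np.arange(len(surface_vertices))
    cand = surface_vertices[candidate_idx]
    tree = cKDTree(cand)
    k = min(len(cand), 8)
    _, nearest = tree.query(positions, k=k)
    nearest = np.atleast_2d(nearest)
    used: set[int] = set()
    attached = np.empty(len(positions), dtype=np.int64)
    for i, row in enumerate(nearest):
        pick = next((j for j in row if j not in used), None)
        if pick is None:  # fall back to exhaustive search
            d = np.linalg.norm(cand - positions[i], axis=1)
            order = np.argsort(d)
            pick = next(j for j in order if j not in used)
        used.add(int(pick))
        attached[i] = candidate_idx[pick]
    return attached


def boundary_surface(mesh: TetVolumeMesh, role="torso") -> TriSurfaceMesh:
    """Extract the closed outer boundary of the tet mesh."""
    faces = boundary_faces(mesh.tetrahedra)
    return TriSurfaceMesh(mesh.vertices, faces, role)


def build_phantom_geometry(spec):
    """Concentric-sphere torso/heart phantom with a Fibonacci electrode lattice.

    ``spec`` is a :class:`volmap.phantom.PhantomSpec`.  Returns
    (torso surface, tet volume mesh, electrodes).  Fully deterministic.
    """
    R = spec.torso_radius_mm
    r_out = spec.heart_outer_radius_mm
    r_in = spec.heart_inner_radius_mm
    if not (R > r_out > r_in > 0):
        raise ValueError("radii must satisfy torso > heart_outer > heart_inner > 0")
    c = np.asarray(spec.heart_offset_mm, dtype=float)
    if np.linalg.norm(c) + r_out >= R:
        raise ValueError("eccentric heart would touch the torso surface")

    torso_surf = icosphere_surface(R, spec.torso_edge_mm, role="torso")
    outer_surf = icosphere_surface(r_out, spec.heart_surface_edge_mm, c, "epicardium")
    inner_surf = icosphere_surface(r_in, spec.heart_surface_edge_mm, c, "endocardium")

    h_h = spec.heart_volume_edge_mm
    h_t = spec.torso_volume_edge_mm
    # fine lattice inside the myocardial band, coarse elsewhere
    fine = _bcc_lattice(c - r_out, c + r_out, 1.09 * h_h)
    rf = np.linalg.norm(fine - c, axis=1)
    fine = fine[(rf > r_in + 0.45 * h_h) & (rf < r_out - 0.45 * h_h)]
    coarse = _bcc_lattice(np.full(3, -R), np.full(3, R), 1.09 * h_t)
    rc = np.linalg.norm(coarse, axis=1)
    rch = np.linalg.norm(coarse - c, axis=1)
    coarse = coarse[
        (rc < R - 0.6 * h_t)
        & ((rch < r_in - 0.6 * h_h) | (rch > r_out + 0.6 * h_t))
    ]
    surf_pts = np.vstack([torso_surf.vertices, outer_surf.vertices,
                          inner_surf.vertices])
    filler = np.vstack([fine, coarse])
    d, _ = cKDTree(surf_pts).query(filler)
    filler = filler[d > 0.5 * h_h]
    points = np.vstack([surf_pts, filler])

    tets = Delaunay(points).simplices
    vols = np.abs(tet_volumes(points, tets))
    tets = tets[vols > 1e-7 * np.median(vols)]
    r_heart = np.linalg.norm(points - c, axis=1)
    tol = 1e-6
    mask = (r_heart >= r_in - tol) & (r_heart <= r_out + tol)
    cut = getattr(spec, "heart_truncation_z_mm", None)
    if cut is not None:
        mask &= (points[:, 2] - c[2]) < cut
    mask[: len(torso_surf.vertices)] = False
    volume = TetVolumeMesh(points, tets, mask).orient().validate()

    dirs = fibonacci_directions(spec.electrode_count)
    positions = R * dirs
    boundary_idx = np.arange(len(torso_surf.vertices))
    attached = attach_electrodes(positions, points, boundary_idx)
    electrodes = ElectrodeSet(positions, attached)
    return torso_surf, volume, electrodes
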