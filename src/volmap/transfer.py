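"""Transfer operators linking cardiac unknowns to body-surface potentials.

Two operators are assembled:

* ``A`` (epicardial): collocation boundary elements for the Cauchy problem
  of Laplace's equation in the homogeneous annulus between the heart and an
  insulated torso, relating epicardial potentials h to torso potentials g.
* ``B`` (volumetric): finite-element Neumann Green's functions of the
  Poisson problem on the full torso volume.  Row i holds G(y_i, x_j): the
  potential at heart node x_j per unit point source at electrode y_i, with
  the insulated-boundary return flux -1/Area.  By reciprocity the same
  numbers map a unit source at x_j to the potential at y_i, so ``B`` (times
  the nodal volume quadrature) predicts electrode potentials from a source
  field.

Both operators assume a homogeneous unit conductivity, so absolute source
units are arbitrary; only relative amplitudes and timings are meaningful.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import yaml
from scipy.special import eval_legendre

from . import fem
from .mesh import (
    ElectrodeSet,
    TetVolumeMesh,
    TriSurfaceMesh,
    attach_electrodes,
    solid_angles,
    winding_number,
)

__all__ = [
    "TransferMatrixA",
    "TransferMatrixB",
    "assemble_bem_laplace",
    "assemble_green_transfer",
    "analytic_sphere_green",
    "save_transfer_matrix",
    "load_transfer_matrix",
]


def _mesh_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


@dataclass
class TransferMatrixA:
    """Dense M x N epicardial transfer operator (electrodes x heart-surface nodes)."""

    matrix: np.ndarray
    torso_hash: str
    heart_hash: str

    @property
    def shape(self):
        return self.matrix.shape

    def predict(self, h: np.ndarray) -> np.ndarray:
        """Torso-electrode potentials from epicardial potentials."""
        return self.matrix @ h


@dataclass
class TransferMatrixB:
    """Dense M x P Green's-function operator (electrodes x heart-volume nodes).

    Entries are Green's-function values; rows are zero-meaned over heart
    nodes (gauge tag ``row-zero-mean``).  Predictions use the lumped volume
    quadrature, g = B diag(w) f, so the row gauge is provably irrelevant for
    any source satisfying the existence condition w . f = 0.
    """

    matrix: np.ndarray
    heart_nodes: np.ndarray
    gauge: str = "row-zero-mean"
    mesh_hash: str = ""

    @property
    def shape(self):
        return self.matrix.shape

    def predict(self, f: np.ndarray, weights) -> np.ndarray:
        g = self.matrix @ (weights.weights[self.heart_nodes][:, None] * f)
        return g - g.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# epicardial BEM (Laplace / Cauchy problem)
# ---------------------------------------------------------------------------

def _double_layer(surface: TriSurfaceMesh, obs: np.ndarray) -> np.ndarray:
    """D[i, j]: potential at obs i of a unit-density double layer lumped to
    vertex j (linear basis, 1/3 of each adjacent triangle's solid angle)."""
    tri_pts = surface.vertices[surface.triangles]
    om = solid_angles(tri_pts, obs)  # (n_obs, n_tri)
    n = len(surface.vertices)
    D = np.zeros((len(obs), n))
    coef = -om / (4.0 * np.pi * 3.0)
    for k in range(3):
        np.add.at(D.T, surface.triangles[:, k], coef.T)
    return D


def _single_layer(surface: TriSurfaceMesh, obs: np.ndarray,
                  obs_vertex_idx: np.ndarray | None = None) -> np.ndarray:
    """S[i, j]: single-layer potential at obs i of unit density lumped to
    vertex j.  Centroid quadrature with one-level subdivision for nearby
    triangles and the analytic vertex integral for adjacent ones."""
    tris = surface.triangles
    pts = surface.vertices
    tri_pts = pts[tris]
    centroids = tri_pts.mean(axis=1)
    p0, p1, p2 = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
    areas = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1) / 2.0
    size = np.sqrt(areas)

    d = np.linalg.norm(obs[:, None, :] - centroids[None, :, :], axis=2)
    I = np.where(d > 1e-300, areas[None, :] / np.maximum(d, 1e-300), 0.0)

    near = d < 3.0 * size[None, :]
    if np.any(near):
        # one-level 4-way subdivision refinement for near (non-singular) pairs
        mids = np.stack([(p0 + p1) / 2, (p1 + p2) / 2, (p2 + p0) / 2], axis=1)
        subs = np.stack(
            [
                np.stack([p0, mids[:, 0], mids[:, 2]], axis=1),
                np.stack([mids[:, 0], p1, mids[:, 1]], axis=1),
                np.stack([mids[:, 2], mids[:, 1], p2], axis=1),
                np.stack([mids[:, 0], mids[:, 1], mids[:, 2]], axis=1),
            ],
            axis=1,
        )  # (n_tri, 4, 3, 3)
        io_, it = np.nonzero(near)
        sc = subs[it].mean(axis=2)  # (k, 4, 3)
        dd = np.linalg.norm(sc - obs[io_][:, None, :], axis=2)
        I[io_, it] = (areas[it, None] / 4.0 / np.maximum(dd, 1e-300)).sum(axis=1)

    if obs_vertex_idx is not None:
        # analytic integral of 1/r over triangles adjacent to the collocation
        # vertex: I = d * ln(tan((alpha+beta)/2) / tan(beta/2))
        for ti, tri in enumerate(tris):
            for local, v in enumerate(tri):
                rows = np.flatnonzero(obs_vertex_idx == v)
                if len(rows) == 0:
                    continue
                a = pts[v]
                b, c = pts[tri[(local + 1) % 3]], pts[tri[(local + 2) % 3]]
                ab, ac, bc = b - a, c - a, c - b
                alpha = np.arccos(
                    np.clip(ab @ ac / (np.linalg.norm(ab) * np.linalg.norm(ac)), -1, 1)
                )
                beta = np.arccos(
                    np.clip(-ab @ bc / (np.linalg.norm(ab) * np.linalg.norm(bc)), -1, 1)
                )
                dist = np.linalg.norm(ab) * np.sin(beta)
                val = dist * np.log(
                    np.tan((alpha + beta) / 2.0) / np.tan(beta / 2.0)
                )
                I[rows, ti] = val

    S = np.zeros((len(obs), len(pts)))
    coef = I / (4.0 * np.pi * 3.0)
    for k in range(3):
        np.add.at(S.T, tris[:, k], coef.T)
    return S


def assemble_bem_laplace(
    torso: TriSurfaceMesh,
    epicardium: TriSurfaceMesh,
    electrodes: ElectrodeSet,
) -> TransferMatrixA:
    """Collocation BEM transfer matrix for the epicardial Cauchy problem.

    Vertex collocation on both closed surfaces with linear (lumped) basis;
    insulated torso; the epicardial normal derivative is eliminated through
    the heart-surface single-layer block.  Diagonal (solid-angle) terms are
    fixed by the row-sum closure identity so that constant potentials are
    transferred exactly.
    """
    torso.validate()
    epicardium.validate()
    if not np.all(winding_number(torso, epicardium.vertices) > 0.5):
        raise ValueError("epicardium must lie strictly inside the torso")

    yt = torso.vertices
    yh = epicardium.vertices
    nt, nh = len(yt), len(yh)

    D_TT = _double_layer(torso, yt)
    D_TH = _double_layer(epicardium, yt)
    D_HT = _double_layer(torso, yh)
    D_HH = _double_layer(epicardium, yh)
    S_TH = _single_layer(epicardium, yt)
    S_HH = _single_layer(epicardium, yh, obs_vertex_idx=np.arange(nh))

    # torso-collocation rows:  C_TT phi_T + C_TH phi_H + S_TH Gamma = 0
    C_TT = D_TT.copy()
    C_TH = -D_TH
    np.fill_diagonal(C_TT, 0.0)
    np.fill_diagonal(C_TT, -(C_TT.sum(axis=1) + C_TH.sum(axis=1)))
    # heart-collocation rows:  C_HT phi_T + C_HH phi_H + S_HH Gamma = 0
    C_HT = D_HT
    C_HH = -D_HH
    np.fill_diagonal(C_HH, 0.0)
    np.fill_diagonal(C_HH, -(C_HH.sum(axis=1) + C_HT.sum(axis=1)))

    SinvC_HT = np.linalg.solve(S_HH, C_HT)
    SinvC_HH = np.linalg.solve(S_HH, C_HH)
    lhs = C_TT - S_TH @ SinvC_HT
    rhs = -(C_TH - S_TH @ SinvC_HH)
    A_full = np.linalg.solve(lhs, rhs)

    attached = attach_electrodes(electrodes.positions, yt)
    return TransferMatrixA(
        A_full[attached],
        torso_hash=_mesh_hash(torso.vertices, torso.triangles),
        heart_hash=_mesh_hash(epicardium.vertices, epicardium.triangles),
    )


# ---------------------------------------------------------------------------
# volumetric Green's-function operator (FEM)
# ---------------------------------------------------------------------------

def assemble_green_transfer(
    mesh: TetVolumeMesh,
    electrodes: ElectrodeSet,
    solver: fem.NeumannPoissonSolver | None = None,
) -> TransferMatrixB:
    """One Neumann FEM solve per electrode: unit nodal load at the attached
    boundary vertex balanced by a uniform boundary flux -1/Area.

    Costs M solves (adjoint formulation), not P.  Rows are sampled at heart
    nodes and zero-meaned (gauge), which cannot affect predictions of any
    source satisfying the existence condition.
    """
    faces = fem.boundary_faces(mesh.tetrahedra)
    bnodes = np.unique(faces)
    if not np.all(np.isin(electrodes.attached_vertex, bnodes)):
        raise ValueError("electrode attached vertex not on the mesh boundary")
    node_areas = fem.boundary_node_areas(mesh.vertices, faces)
    area = node_areas.sum()
    if solver is None:
        solver = fem.NeumannPoissonSolver(mesh.vertices, mesh.tetrahedra)
    n = len(mesh.vertices)
    m = len(electrodes)
    rhs = np.tile(-(node_areas / area)[:, None], (1, m))
    rhs[electrodes.attached_vertex, np.arange(m)] += 1.0
    assert np.all(np.abs(rhs.sum(axis=0)) < 1e-10)  # compatible by construction
    sol = solver.solve(rhs)  # (n, m)
    B = sol[mesh.heart_nodes].T.copy()
    B -= B.mean(axis=1, keepdims=True)
    return TransferMatrixB(
        B,
        heart_nodes=mesh.heart_nodes,
        mesh_hash=_mesh_hash(mesh.vertices, mesh.tetrahedra),
    )


# ---------------------------------------------------------------------------
# analytic oracle: Neumann Green's function of the sphere
# ---------------------------------------------------------------------------

def analytic_sphere_green(
    electrode_pos: np.ndarray,
    field_pos: np.ndarray,
    radius: float,
    n_terms: int = 100,
) -> np.ndarray:
    """Truncated Legendre series for the insulated-sphere Green's function.

    For a unit point source at boundary point y with uniform return flux
    -1/(4 pi R^2), the interior potential is

        G(x) = 1/(4 pi R) * sum_{l>=1} (2l+1)/l (r/R)^l P_l(cos gamma)

    up to an additive constant (the Neumann gauge).  The truncation error
    is bounded by a geometric tail in (r/R), so the series is accurate to
    ~(r/R)^n; callers should keep |x| <= ~0.9 R.
    """
    field_pos = np.atleast_2d(field_pos)
    y = np.asarray(electrode_pos, dtype=float)
    r = np.linalg.norm(field_pos, axis=1)
    if np.any(r >= radius):
        raise ValueError("field points must lie strictly inside the sphere")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    yn = y / np.linalg.norm(y)
    mu = np.clip(field_pos @ yn / np.maximum(r, 1e-300), -1.0, 1.0)
    mu = np.where(r > 0, mu, 1.0)
    t = r / radius
    out = np.zeros(len(field_pos))
    for l in range(1, n_terms + 1):
        out += (2 * l + 1) / l * t**l * eval_legendre(l, mu)
    return out / (4.0 * np.pi * radius)


# ---------------------------------------------------------------------------
# serialization: Matrix Market + YAML sidecar
# ---------------------------------------------------------------------------

def save_transfer_matrix(path, tm):
    path = Path(path)
    scipy.io.mmwrite(str(path), np.asarray(tm.matrix))
    meta = {"kind": type(tm).__name__}
    if isinstance(tm, TransferMatrixB):
        meta.update(
            gauge=tm.gauge,
            mesh_hash=tm.mesh_hash,
            heart_nodes=tm.heart_nodes.tolist(),
            element_order="P1",
        )
    else:
        meta.update(torso_hash=tm.torso_hash, heart_hash=tm.heart_hash,
                    basis_order="linear")
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))


def load_transfer_matrix(path):
    path = Path(path)
    mat = np.asarray(scipy.io.mmread(str(path)))
    meta = yaml.safe_load(Path(str(path) + ".yaml").read_text())
    if meta["kind"] == "TransferMatrixB":
        return TransferMatrixB(
            mat,
            heart_nodes=np.asarray(meta["heart_nodes"], dtype=np.int64),
            gauge=meta["gauge"],
            mesh_hash=meta["mesh_hash"],
        )
    return TransferMatrixA(mat, meta["torso_hash"], meta["heart_hash"])
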