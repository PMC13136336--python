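"""First-order (P1) tetrahedral finite elements for the Neumann Poisson problem.

The torso is treated as a homogeneous quasi-static volume conductor, so both
the forward projection of cardiac sources and the Green's-function transfer
rows reduce to solves of the pure-Neumann Laplacian ``K u = b`` with the
one-dimensional constant nullspace handled exactly.  The solver factorises the
augmented saddle-point system

    [ K   1 ] [u]   [b]
    [ 1^T 0 ] [mu] = [0]

once and reuses the factorisation across right-hand sides (time samples and
electrodes), which is what makes assembling the M x P transfer matrix cost M
solves rather than P.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "tet_volumes",
    "p1_gradients",
    "assemble_stiffness",
    "boundary_faces",
    "boundary_node_areas",
    "NeumannPoissonSolver",
]


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of each tetrahedron (positive for correct orientation)."""
    a = vertices[tets[:, 0]]
    d1 = vertices[tets[:, 1]] - a
    d2 = vertices[tets[:, 2]] - a
    d3 = vertices[tets[:, 3]] - a
    return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0


def p1_gradients(vertices: np.ndarray, tets: np.ndarray):
    """Gradients of the four linear shape functions on each tet.

    Returns (grads, vols): grads has shape (n_tets, 4, 3) with
    grads[k, i] = grad of the barycentric coordinate of local node i on tet k.
    """
    vols = tet_volumes(vertices, tets)
    if np.any(vols <= 0):
        bad = int(np.argmin(vols))
        raise ValueError(f"non-positive tet volume at element {bad}")
    n = len(tets)
    grads = np.empty((n, 4, 3))
    # grad(lambda_i) = N_i / (6 V) with N_i the inward-scaled face normal
    # opposite node i.
    for i in range(4):
        others = [j for j in range(4) if j != i]
        p0 = vertices[tets[:, others[0]]]
        p1 = vertices[tets[:, others[1]]]
        p2 = vertices[tets[:, others[2]]]
        nvec = np.cross(p1 - p0, p2 - p0) / 2.0  # face area normal
        # orient towards node i
        toi = vertices[tets[:, i]] - p0
        sign = np.sign(np.einsum("ij,ij->i", nvec, toi))
        grads[:, i, :] = nvec * (sign / (3.0 * vols))[:, None]
    return grads, vols


def assemble_stiffness(
    vertices: np.ndarray,
    tets: np.ndarray,
    conductivity: np.ndarray | float = 1.0,
) -> sp.csr_matrix:
    """Assemble the P1 stiffness matrix K_ij = sum_K sigma_K V_K grad(i).grad(j).

    ``conductivity`` is a scalar or a per-tet array (isotropic).
    """
    grads, vols = p1_gradients(vertices, tets)
    sigma = np.broadcast_to(np.asarray(conductivity, dtype=float), (len(tets),))
    # local 4x4 blocks, vectorised
    local = np.einsum("kid,kjd->kij", grads, grads) * (sigma * vols)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (local.reshape(-1), (rows, cols)), shape=(len(vertices), len(vertices))
    )
    return K.tocsr()


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Triangular faces of the tet mesh that belong to exactly one tet.

    Faces are returned with outward orientation (node order such that the
    normal points away from the owning tet's fourth node).
    """
    # local faces with outward orientation for a positively oriented tet
    face_ids = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, face_ids].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return faces[counts[inv] == 1]


def boundary_node_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Lumped boundary areas: each boundary triangle contributes area/3 per node."""
    p0, p1, p2 = (vertices[faces[:, i]] for i in range(3))
    areas = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1) / 2.0
    out = np.zeros(len(vertices))
    np.add.at(out, faces.reshape(-1), np.repeat(areas / 3.0, 3))
    return out


class NeumannPoissonSolver:
    """Factorised solver for -div(sigma grad u) = b with insulated boundary.

    Solutions are fixed to zero mean over all mesh nodes.  For an
    incompatible right-hand side (sum(b) != 0) the solver returns the
    least-squares-consistent solution of the projected problem; callers that
    require strict compatibility check it beforehand.
    """

    #: global count of factorised solves, used to assert the M-solve cost
    #: contract of transfer-matrix assembly.
    solve_count: int = 0

    def __init__(self, vertices, tets, conductivity=1.0):
        self.n = len(vertices)
        K = assemble_stiffness(vertices, tets, conductivity)
        one = np.ones((self.n, 1))
        aug = sp.bmat([[K, one], [one.T, None]], format="csc")
        self._lu = spla.splu(aug)
        self.stiffness = K

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve for one RHS (n,) or a batch (n, k); returns same shape."""
        b = np.asarray(b, dtype=float)
        single = b.ndim == 1
        B = b[:, None] if single else b
        rhs = np.vstack([B, np.zeros((1, B.shape[1]))])
        sol = self._lu.solve(rhs)
        NeumannPoissonSolver.solve_count += B.shape[1]
        u = sol[:-1]
        return u[:, 0] if single else u
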