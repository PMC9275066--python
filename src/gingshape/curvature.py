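"""Scale-dependent principal-curvature estimation by local quadric fitting.

At every vertex a full quadric Monge patch

    z = a u^2 + b uv + c v^2 + d u + e v + f

is least-squares fitted, in the vertex tangent frame, to all neighbours
reachable through mesh edges while staying inside a Euclidean ball of the
chosen *diameter* around the vertex.  The diameter is the spatial scale of
the analysis: features smaller than it are smoothed away by the fit, which
is what makes the estimate usable on noisy scanner meshes.

Principal curvatures come from the Weingarten map built from the fitted
first and second fundamental forms.  The sign convention is
"convex outward = positive": with outward vertex normals a bulge (e.g. a
swollen gingival margin) has positive curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .mesh_io import TriangleMesh

__all__ = [
    "LocalQuadric",
    "PrincipalCurvatureField",
    "collect_neighborhood",
    "fit_local_quadric",
    "principal_from_quadric",
    "estimate_curvature",
]

MIN_FIT_POINTS = 6  # a 6-parameter quadric needs at least 6 samples


@dataclass
class LocalQuadric:
    """Fitted quadric at one vertex, in its right-handed tangent frame."""

    vertex: int
    frame: np.ndarray  # (3, 3): rows t1, t2, n
    coeffs: np.ndarray  # (6,): a, b, c, d, e, f
    n_points: int
    rank_deficient: bool = False


@dataclass
class PrincipalCurvatureField:
    """Per-vertex principal curvatures (1/mm) and directions at one diameter."""

    kmin: np.ndarray
    kmax: np.ndarray
    dir_min: np.ndarray  # (n, 3) unit, tangent
    dir_max: np.ndarray  # (n, 3) unit, tangent
    diameter_mm: float
    n_neighbors: np.ndarray  # per-vertex count used in the fit
    umbilic: np.ndarray  # bool: kmin == kmax within tolerance
    fallback: np.ndarray  # bool: ball had < 6 points, rings were expanded
    mesh_id: str = ""

    @property
    def n_vertices(self) -> int:
        return len(self.kmin)


# ---------------------------------------------------------------------------
# adjacency helpers


def _vertex_adjacency(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """CSR (indptr, indices) of the undirected vertex graph."""
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.concatenate([e, e[:, ::-1]])
    e = np.unique(e, axis=0)
    n = mesh.n_vertices
    adj = csr_matrix((np.ones(len(e), dtype=np.int8), (e[:, 0], e[:, 1])), shape=(n, n))
    return adj.indptr, adj.indices


def _ball_bfs(
    seed: int,
    candidates: np.ndarray,
    indptr: np.ndarray,
    indices: np.ndarray,
    stamp: np.ndarray,
    token: int,
) -> list[int]:
    """Vertices edge-reachable from ``seed`` through the candidate ball."""
    stamp[candidates] = token
    out = [seed]
    stack = [seed]
    stamp[seed] = -token - 1  # visited marker
    while stack:
        v = stack.pop()
        for w in indices[indptr[v] : indptr[v + 1]]:
            if stamp[w] == token:
                stamp[w] = -token - 1
                out.append(w)
                stack.append(w)
    return out


def collect_neighborhood(mesh: TriangleMesh, vertex: int, diameter_mm: float) -> np.ndarray:
    """Neighbourhood of one vertex: the edge-connected part of the Euclidean
    ball of radius ``diameter_mm / 2`` that contains the seed.

    Breadth-first traversal of mesh edges never leaves the ball, so nearby
    but disconnected geometry (an adjacent tooth) is never borrowed.  The
    seed itself is always included.  Returns sorted vertex indices.
    """
    if not diameter_mm > 0:
        raise ValueError("diameter_mm must be > 0")
    indptr, indices = _vertex_adjacency(mesh)
    tree = cKDTree(mesh.vertices)
    cand = np.asarray(tree.query_ball_point(mesh.vertices[vertex], diameter_mm / 2.0), dtype=np.int64)
    stamp = np.zeros(mesh.n_vertices, dtype=np.int64)
    return np.sort(np.asarray(_ball_bfs(vertex, cand, indptr, indices, stamp, 1), dtype=np.int64))


def _ring_expand(
    seed: int,
    have: list[int],
    indptr: np.ndarray,
    indices: np.ndarray,
    minimum: int,
) -> list[int]:
    """Grow topological rings around ``seed`` until at least ``minimum`` points."""
    seen = set(have)
    frontier = list(have)
    while len(seen) < minimum and frontier:
        nxt = []
        for v in frontier:
            for w in indices[indptr[v] : indptr[v + 1]]:
                if w not in seen:
                    seen.add(int(w))
                    nxt.append(int(w))
        frontier = nxt
    return sorted(seen)


# ---------------------------------------------------------------------------
# tangent frames and quadric fitting


def _tangent_frame(normal: np.ndarray) -> np.ndarray:
    """Deterministic right-handed orthonormal frame (t1, t2, n)."""
    n = normal / np.linalg.norm(normal)
    e = np.zeros(3)
    e[np.argmin(np.abs(n))] = 1.0
    t1 = np.cross(e, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.vstack([t1, t2, n])


def fit_local_quadric(
    mesh: TriangleMesh,
    vertex: int,
    neighbors: np.ndarray,
) -> LocalQuadric:
    """Least-squares quadric through the neighbourhood, in the seed frame.

    The residual is minimised along the seed normal (z of the frame).  The
    constant term is part of the model, so the fitted patch need not pass
    through the vertex — this is what filters measurement noise.
    """
    neighbors = np.asarray(neighbors, dtype=np.int64)
    if len(neighbors) < MIN_FIT_POINTS:
        raise ValueError(f"need at least {MIN_FIT_POINTS} neighbours, got {len(neighbors)}")
    frame = _tangent_frame(mesh.vertex_normals[vertex])
    rel = (mesh.vertices[neighbors] - mesh.vertices[vertex]) @ frame.T
    u, v, z = rel[:, 0], rel[:, 1], rel[:, 2]
    A = np.column_stack([u * u, u * v, v * v, u, v, np.ones_like(u)])
    coeffs, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    deficient = rank < 6
    if deficient:
        # ridge fallback keeps the field hole-free; the vertex stays flagged
        AtA = A.T @ A + 1e-10 * np.eye(6)
        coeffs = np.linalg.solve(AtA, A.T @ z)
    return LocalQuadric(
        vertex=int(vertex),
        frame=frame,
        coeffs=np.asarray(coeffs, dtype=np.float64),
        n_points=len(neighbors),
        rank_deficient=bool(deficient),
    )


UMBILIC_ATOL = 1e-12


def principal_from_quadric(q: LocalQuadric) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Principal curvatures and 3D directions of the fitted patch at (0, 0).

    Returns ``(kmin, kmax, dir_min, dir_max)`` with ``kmax >= kmin``.  The
    sign follows the graph convention of the patch itself: bending *toward*
    the frame normal is positive (``z = (u^2+v^2)/2`` has k = +1).
    :func:`estimate_curvature` flips this to convex-outward-positive.
    """
    a, b, c, d, e, _f = q.coeffs
    w2 = 1.0 + d * d + e * e
    w = np.sqrt(w2)
    I = np.array([[1.0 + d * d, d * e], [d * e, 1.0 + e * e]])
    II = np.array([[2.0 * a, b], [b, 2.0 * c]]) / w
    # generalized symmetric eigenproblem II y = k I y via Cholesky of I;
    # guaranteed real, eigenvectors I-orthogonal (hence 3D-orthogonal after
    # mapping through the surface basis X_u, X_v).
    l11 = np.sqrt(I[0, 0])
    l21 = I[1, 0] / l11
    l22 = np.sqrt(I[1, 1] - l21 * l21)
    Linv = np.array([[1.0 / l11, 0.0], [-l21 / (l11 * l22), 1.0 / l22]])
    C = Linv @ II @ Linv.T
    C = 0.5 * (C + C.T)
    kvals, Y = np.linalg.eigh(C)
    E = Linv.T @ Y  # columns: (u, v) eigvecs, I-orthonormal
    t1, t2, n = q.frame
    Xu = t1 + d * n
    Xv = t2 + e * n
    dirs = []
    for j in range(2):
        vec = E[0, j] * Xu + E[1, j] * Xv
        dirs.append(vec / np.linalg.norm(vec))
    kmin, kmax = float(kvals[0]), float(kvals[1])
    dir_min, dir_max = dirs[0], dirs[1]
    scale = max(1.0, abs(kmin), abs(kmax))
    if kmax - kmin <= UMBILIC_ATOL * scale:
        # umbilic: any orthonormal tangent pair is principal
        dir_min, dir_max = t1.copy(), t2.copy()
    return kmin, kmax, dir_min, dir_max


# ---------------------------------------------------------------------------
# whole-mesh driver


def estimate_curvature(mesh: TriangleMesh, diameter_mm: float) -> PrincipalCurvatureField:
    """Per-vertex principal curvatures at one estimation diameter.

    Sign convention: with outward normals, a locally convex (bulging)
    surface has positive curvature, so a sphere of radius r gives
    ``kmin = kmax = +1/r``.  Vertices whose ball holds fewer than 6 points
    fall back to expanding topological rings and are flagged.
    """
    if not diameter_mm > 0:
        raise ValueError("diameter_mm must be > 0")
    n = mesh.n_vertices
    if n < MIN_FIT_POINTS:
        raise ValueError(f"mesh has {n} vertices; need at least {MIN_FIT_POINTS}")
    indptr, indices = _vertex_adjacency(mesh)
    tree = cKDTree(mesh.vertices)
    balls = tree.query_ball_point(mesh.vertices, diameter_mm / 2.0, workers=-1)

    kmin = np.empty(n)
    kmax = np.empty(n)
    dir_min = np.empty((n, 3))
    dir_max = np.empty((n, 3))
    n_neighbors = np.empty(n, dtype=np.int64)
    umbilic = np.zeros(n, dtype=bool)
    fallback = np.zeros(n, dtype=bool)
    stamp = np.zeros(n, dtype=np.int64)

    verts = mesh.vertices
    normals = mesh.vertex_normals
    for i in range(n):
        cand = np.asarray(balls[i], dtype=np.int64)
        nbrs = _ball_bfs(i, cand, indptr, indices, stamp, i + 1)
        if len(nbrs) < MIN_FIT_POINTS:
            nbrs = _ring_expand(i, nbrs, indptr, indices, MIN_FIT_POINTS)
            fallback[i] = True
        nbrs_arr = np.asarray(nbrs, dtype=np.int64)
        frame = _tangent_frame(normals[i])
        rel = (verts[nbrs_arr] - verts[i]) @ frame.T
        A = np.column_stack([rel[:, 0] ** 2, rel[:, 0] * rel[:, 1], rel[:, 1] ** 2, rel])
        # columns: u^2, uv, v^2, u, v, 1
        A[:, 5] = 1.0
        z = rel[:, 2].copy()
        coeffs, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
        if rank < 6:
            AtA = A.T @ A + 1e-10 * np.eye(6)
            coeffs = np.linalg.solve(AtA, A.T @ z)
            fallback[i] = True
        q = LocalQuadric(i, frame, coeffs, len(nbrs_arr), rank < 6)
        k1, k2, d1, d2 = principal_from_quadric(q)
        # flip graph sign -> convex-outward-positive; order swaps with sign
        kmin[i], kmax[i] = -k2, -k1
        dir_min[i], dir_max[i] = d2, d1
        n_neighbors[i] = len(nbrs_arr)
        scale = max(1.0, abs(k1), abs(k2))
        umbilic[i] = (k2 - k1) <= UMBILIC_ATOL * scale

    return PrincipalCurvatureField(
        kmin=kmin,
        kmax=kmax,
        dir_min=dir_min,
        dir_max=dir_max,
        diameter_mm=float(diameter_mm),
        n_neighbors=n_neighbors,
        umbilic=umbilic,
        fallback=fallback,
    )
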