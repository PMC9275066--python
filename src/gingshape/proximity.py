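"""Closest-point queries on a triangle mesh.

A cKDTree over triangle centroids proposes candidate triangles inside a
radius that provably contains the closest one (nearest centroid distance
plus the largest triangle circumdiameter); the exact closest point is then
found per candidate with the standard barycentric-region point-triangle
test, vectorized over all (point, triangle) pairs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import TriangleMesh

__all__ = ["MeshProximity", "closest_point_on_mesh"]


def _closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on each triangle (a,b,c) to each paired query point p."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)[:, None]
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab * ab)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)[:, None]
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac * ac)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)[:, None]
        assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc * (c - b))
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = (vb / denom)[:, None]
        w = (vc / denom)[:, None]
        assign(np.ones(len(p), dtype=bool), a + v * ab + w * ac)
    return out


class MeshProximity:
    """Reusable closest-point structure for one mesh."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self._tri = tri
        self._centroids = tri.mean(axis=1)
        # max distance from a centroid to its own triangle's vertices
        self._reach = float(np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max())
        self._tree = cKDTree(self._centroids)

    def on_surface(self, points: np.ndarray):
        """(closest_points, distances, triangle_indices) for query points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d_near, _ = self._tree.query(points, k=1, workers=-1)
        radii = d_near + 2.0 * self._reach + 1e-9
        cand = self._tree.query_ball_point(points, radii, workers=-1)
        counts = np.fromiter((len(c) for c in cand), dtype=np.int64, count=len(points))
        pt_idx = np.repeat(np.arange(len(points)), counts)
        tri_idx = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])
        tri = self._tri[tri_idx]
        cp = _closest_point_triangles(points[pt_idx], tri[:, 0], tri[:, 1], tri[:, 2])
        d2 = np.einsum("ij,ij->i", points[pt_idx] - cp, points[pt_idx] - cp)
        # per-point argmin via lexsort on (point, distance)
        order = np.lexsort((d2, pt_idx))
        first = np.searchsorted(pt_idx[order], np.arange(len(points)))
        best = order[first]
        return cp[best], np.sqrt(d2[best]), tri_idx[best]


def closest_point_on_mesh(mesh: TriangleMesh, points: np.ndarray):
    """One-shot convenience wrapper around :class:`MeshProximity`."""
    return MeshProximity(mesh).on_surface(points)
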