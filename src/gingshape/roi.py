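"""Margin-band ROI construction.

The region of interest for gingival shape analysis is a band that starts at
the gingival-margin landmark curve and extends a fixed on-surface distance
(default 3 mm) in the apical direction.  The band is split into *central*
regions (facing the mid-tooth surface, between a tooth's mesial and distal
line angles) and *interdental* regions (the papilla areas between teeth).

The apical direction is a single global unit vector per scan (the occlusal
axis surrogate); the interactive anatomy-driven choice of the original
workflow is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_io import CurveRole, LandmarkCurve, TriangleMesh
from .proximity import MeshProximity

log = logging.getLogger(__name__)

__all__ = [
    "ROISelection",
    "offset_margin_apically",
    "select_band",
    "split_by_line_angles",
    "build_tooth_rois",
    "save_rois_csv",
    "load_rois_csv",
]


@dataclass
class ROISelection:
    """A named set of vertex indices on a specific mesh."""

    vertex_indices: np.ndarray
    kind: str  # central | interdental | band
    tooth_label: str = ""
    mesh_id: str = ""
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertex_indices = np.unique(np.asarray(self.vertex_indices, dtype=np.int64))
        if self.kind not in ("central", "interdental", "band"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if len(self.vertex_indices) == 0:
            raise ValueError("ROI selection is empty")

    def __len__(self) -> int:
        return len(self.vertex_indices)


# ---------------------------------------------------------------------------
# polyline distance helpers


def _closest_on_polyline(points: np.ndarray, curve: np.ndarray, chunk: int = 2048):
    """Closest point on a polyline for each query point.

    Returns (closest_points, distances).  Vectorized per segment, chunked
    over query points to bound memory.
    """
    a = curve[:-1]  # (s, 3)
    ab = curve[1:] - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2[ab2 == 0] = 1.0
    best_pts = np.empty_like(points)
    best_d2 = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]  # (q, 3)
        ap = p[:, None, :] - a[None, :, :]  # (q, s, 3)
        t = np.clip(np.einsum("qsj,sj->qs", ap, ab) / ab2, 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d2 = np.einsum("qsj->qs", (p[:, None, :] - proj) ** 2)
        j = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        best_pts[lo : lo + chunk] = proj[rows, j]
        best_d2[lo : lo + chunk] = d2[rows, j]
    return best_pts, np.sqrt(best_d2)


def _polyline_min_separation(c1: np.ndarray, c2: np.ndarray) -> float:
    _, d = _closest_on_polyline(c1, c2)
    return float(d.min())


# ---------------------------------------------------------------------------
# apical offset by surface marching


def offset_margin_apically(
    mesh: TriangleMesh,
    margin: LandmarkCurve,
    apical_direction: np.ndarray,
    offset_mm: float = 3.0,
    step_mm: float = 0.1,
) -> LandmarkCurve:
    """Project the margin curve apically *along the surface* by ``offset_mm``.

    Each margin point marches in steps of ``step_mm``: the apical direction
    is projected onto the local tangent plane, the point advances, and is
    re-projected onto the mesh; accumulated on-surface path length stops at
    ``offset_mm``.  Points whose march stalls at a mesh boundary are clamped
    there and counted in a logged warning.
    """
    a = np.asarray(apical_direction, dtype=float)
    if abs(np.linalg.norm(a) - 1.0) > 1e-6:
        raise ValueError("apical_direction must be a unit vector")
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    prox = MeshProximity(mesh)
    pos0, dist0, _ = prox.on_surface(margin.points)
    if dist0.max() > 0.5:
        raise ValueError(
            f"margin must lie on/near the surface (max distance {dist0.max():.3f} mm > 0.5 mm)"
        )
    if offset_mm == 0:
        return LandmarkCurve(margin.points.copy(), role=CurveRole.APICAL, closed=margin.closed)

    pos = pos0.copy()
    remaining = np.full(len(pos), float(offset_mm))
    stalled = np.zeros(len(pos), dtype=bool)
    fv = mesh.vertices[mesh.faces]
    face_normals = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0])
    face_normals /= np.linalg.norm(face_normals, axis=1)[:, None]
    max_iter = int(np.ceil(offset_mm / step_mm)) * 4 + 10
    for _ in range(max_iter):
        active = (remaining > 1e-12) & ~stalled
        if not active.any():
            break
        p = pos[active]
        _, _, tri = prox.on_surface(p)
        n = face_normals[tri]
        dir_t = a[None, :] - np.einsum("ij,j->i", n, a)[:, None] * n
        norm = np.linalg.norm(dir_t, axis=1)
        flat = norm < 1e-9
        norm[flat] = 1.0
        dir_t /= norm[:, None]
        step = np.minimum(step_mm, remaining[active])
        raw = p + dir_t * step[:, None]
        proj, _, _ = prox.on_surface(raw)
        advanced = np.linalg.norm(proj - p, axis=1)
        stuck = flat | (advanced < 0.25 * step)
        idx = np.flatnonzero(active)
        pos[idx[~stuck]] = proj[~stuck]
        remaining[idx[~stuck]] -= advanced[~stuck]
        stalled[idx[stuck]] = True
    n_clamped = int(stalled.sum())
    if n_clamped:
        log.warning(
            "apical offset: %d point(s) reached the mesh boundary before %.2f mm and were clamped",
            n_clamped,
            offset_mm,
        )
    return LandmarkCurve(pos, role=CurveRole.APICAL, closed=margin.closed)


# ---------------------------------------------------------------------------
# band selection and splitting


def _infer_apical_direction(margin: LandmarkCurve, apical: LandmarkCurve) -> np.ndarray:
    d = apical.points.mean(axis=0) - margin.points.mean(axis=0)
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("cannot infer apical direction: curves have coincident centroids")
    return d / n


def select_band(
    mesh: TriangleMesh,
    margin: LandmarkCurve,
    apical_boundary: LandmarkCurve,
    apical_direction: np.ndarray | None = None,
) -> ROISelection:
    """Vertices lying between the margin and the apical boundary curve.

    A vertex is in the band when it sits on the apical side of its closest
    margin point and on the coronal side of its closest apical-boundary
    point (both boundaries inclusive, so the margin line itself belongs to
    the band).  ``apical_direction`` defaults to the direction between the
    two curve centroids.
    """
    if apical_direction is None:
        a = _infer_apical_direction(margin, apical_boundary)
    else:
        a = np.asarray(apical_direction, dtype=float)
        a = a / np.linalg.norm(a)
    if _polyline_min_separation(margin.points, apical_boundary.points) < 1e-9:
        raise ValueError("margin and apical boundary curves touch or intersect")
    v = mesh.vertices
    m_pts, _ = _closest_on_polyline(v, margin.points)
    a_pts, _ = _closest_on_polyline(v, apical_boundary.points)
    tol = 1e-9
    below_margin = np.einsum("ij,j->i", v - m_pts, a) >= -tol
    above_apical = np.einsum("ij,j->i", v - a_pts, a) <= tol
    sel = np.flatnonzero(below_margin & above_apical)
    if len(sel) == 0:
        raise ValueError("band selection is empty")
    return ROISelection(
        sel,
        kind="band",
        provenance={"offset_direction": a.tolist()},
    )


def _cutting_plane(curve: LandmarkCurve, apical_direction: np.ndarray, mesh: TriangleMesh):
    """Plane through the curve containing the apical direction.

    Returns (centroid, unit normal).  The normal is the least-variance
    direction of the curve points within the subspace orthogonal to the
    apical direction.  A curve running purely along the apical direction
    leaves that underdetermined; then the plane is anchored to the surface
    instead: normal = curve direction x mean surface normal along the curve.
    """
    a = np.asarray(apical_direction, dtype=float)
    a = a / np.linalg.norm(a)
    c = curve.points.mean(axis=0)
    rel = curve.points - c
    # basis of the plane orthogonal to a
    e = np.zeros(3)
    e[np.argmin(np.abs(a))] = 1.0
    b1 = np.cross(e, a)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(a, b1)
    q = rel @ np.column_stack([b1, b2])  # (k, 2)
    w, vec = np.linalg.eigh(q.T @ q)
    extent_perp = np.sqrt(max(w[1], 0.0))
    extent_total = np.linalg.norm(rel, axis=1).max()
    if extent_perp < 0.05 * extent_total + 1e-12:
        # degenerate: curve parallel to the apical axis
        from scipy.spatial import cKDTree

        _, idx = cKDTree(mesh.vertices).query(curve.points)
        nbar = mesh.vertex_normals[idx].mean(axis=0)
        dir3 = rel[np.argmax(np.linalg.norm(rel, axis=1))]
        nrm = np.cross(dir3, nbar)
        nrm -= (nrm @ a) * a  # keep the apical direction in the plane
        norm = np.linalg.norm(nrm)
        if norm < 1e-9:
            raise ValueError("cannot orient a cutting plane for this line-angle curve")
        return c, nrm / norm
    nrm = vec[0, 0] * b1 + vec[1, 0] * b2  # smallest-variance direction
    return c, nrm / np.linalg.norm(nrm)


def split_by_line_angles(
    band: ROISelection,
    mesh: TriangleMesh,
    mesial: LandmarkCurve,
    distal: LandmarkCurve,
    apical_direction: np.ndarray,
    tooth_label: str = "",
) -> tuple[ROISelection, ROISelection]:
    """Split a band into central (between the two line-angle cutting planes)
    and interdental (the rest).  Disjoint by construction; their union is
    the band."""
    c_m, n_m = _cutting_plane(mesial, apical_direction, mesh)
    c_d, n_d = _cutting_plane(distal, apical_direction, mesh)
    # orient each normal toward the other curve
    if np.dot(c_d - c_m, n_m) < 0:
        n_m = -n_m
    if np.dot(c_m - c_d, n_d) < 0:
        n_d = -n_d
    v = mesh.vertices[band.vertex_indices]
    s_m = (v - c_m) @ n_m
    s_d = (v - c_d) @ n_d
    inside = (s_m >= 0) & (s_d >= 0)
    if not inside.any():
        raise ValueError("line-angle planes do not enclose any band vertices")
    if inside.all():
        raise ValueError("line-angle planes do not cross the band")
    central = ROISelection(
        band.vertex_indices[inside], kind="central", tooth_label=tooth_label, mesh_id=band.mesh_id
    )
    inter = ROISelection(
        band.vertex_indices[~inside],
        kind="interdental",
        tooth_label=tooth_label,
        mesh_id=band.mesh_id,
    )
    return central, inter


def build_tooth_rois(
    mesh: TriangleMesh,
    band: ROISelection,
    line_angle_pairs: list[tuple[LandmarkCurve, LandmarkCurve]],
    apical_direction: np.ndarray,
    tooth_labels: list[str] | None = None,
) -> tuple[list[ROISelection], list[ROISelection]]:
    """Partition a whole-arch band into per-tooth central ROIs and per-gap
    interdental ROIs.

    ``line_angle_pairs`` lists (mesial, distal) curves per tooth in arch
    order.  Gap j collects the band vertices between tooth j's distal plane
    and tooth j+1's mesial plane; leftover vertices (exactly on a plane, or
    beyond the outermost line angles) are assigned to the adjacent region
    with the best plane-side score so the result is an exact partition.
    """
    n_teeth = len(line_angle_pairs)
    if n_teeth == 0:
        raise ValueError("need at least one line-angle pair")
    if tooth_labels is None:
        tooth_labels = [f"T{i + 1:02d}" for i in range(n_teeth)]
    planes = []  # per tooth: (c_m, n_m, c_d, n_d)
    for mesial, distal in line_angle_pairs:
        c_m, n_m = _cutting_plane(mesial, apical_direction, mesh)
        c_d, n_d = _cutting_plane(distal, apical_direction, mesh)
        if np.dot(c_d - c_m, n_m) < 0:
            n_m = -n_m
        if np.dot(c_m - c_d, n_d) < 0:
            n_d = -n_d
        planes.append((c_m, n_m, c_d, n_d))

    v = mesh.vertices[band.vertex_indices]
    # per-tooth inside score: min of the two signed plane distances
    tooth_score = np.stack(
        [np.minimum((v - cm) @ nm, (v - cd) @ nd) for cm, nm, cd, nd in planes], axis=1
    )
    central_mask = tooth_score >= 0
    if (central_mask.sum(axis=1) > 1).any():
        raise ValueError("line-angle planes of different teeth overlap")
    label = np.full(len(v), -1, dtype=np.int64)  # tooth index or -1
    ti = np.argmax(tooth_score, axis=1)
    has = central_mask.any(axis=1)
    label[has] = ti[has]

    centrals = [
        ROISelection(
            band.vertex_indices[label == i],
            kind="central",
            tooth_label=tooth_labels[i],
            mesh_id=band.mesh_id,
        )
        for i in range(n_teeth)
    ]

    interdentals: list[ROISelection] = []
    rest = label < 0
    if n_teeth > 1:
        # gap score: between tooth j's distal and tooth j+1's mesial plane
        gap_score = np.stack(
            [
                np.minimum(
                    -((v - planes[j][2]) @ planes[j][3]),
                    -((v - planes[j + 1][0]) @ planes[j + 1][1]),
                )
                for j in range(n_teeth - 1)
            ],
            axis=1,
        )
        gj = np.argmax(gap_score, axis=1)
        for j in range(n_teeth - 1):
            sel = rest & (gj == j)
            if sel.any():
                interdentals.append(
                    ROISelection(
                        band.vertex_indices[sel],
                        kind="interdental",
                        tooth_label=f"{tooth_labels[j]}-{tooth_labels[j + 1]}",
                        mesh_id=band.mesh_id,
                    )
                )
    elif rest.any():
        interdentals.append(
            ROISelection(band.vertex_indices[rest], kind="interdental", mesh_id=band.mesh_id)
        )
    return centrals, interdentals


# ---------------------------------------------------------------------------
# persistence


def save_rois_csv(rois: list[ROISelection], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "vertex_index": r.vertex_indices,
                "kind": r.kind,
                "tooth_label": r.tooth_label,
            }
        )
        for r in rois
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def load_rois_csv(path: str | Path) -> list[ROISelection]:
    df = pd.read_csv(Path(path))
    df["tooth_label"] = df["tooth_label"].fillna("")
    out = []
    for (kind, label), grp in df.groupby(["kind", "tooth_label"], sort=True):
        out.append(ROISelection(grp["vertex_index"].to_numpy(), kind=kind, tooth_label=str(label)))
    return out
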