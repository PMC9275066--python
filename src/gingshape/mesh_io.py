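"""Mesh and landmark-curve I/O.

Intraoral scanners export surfaces as STL; the analysis pipeline re-exports
them as PLY so that per-vertex curvature values can travel with the geometry
as named float scalar properties.  Landmark curves (gingival margin, line
angles) are plain x,y,z CSV polylines in millimetres.

All geometry in this package is in millimetres; meshes carry a ``units``
flag and nothing ever rescales silently.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

__all__ = [
    "Measure",
    "CurveRole",
    "TriangleMesh",
    "ScalarField",
    "LandmarkCurve",
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "write_ply_with_fields",
    "read_ply_with_fields",
    "read_landmark_csv",
    "write_landmark_csv",
    "field_property_name",
    "parse_field_property_name",
]

#: tolerance (mm) used when welding duplicated STL vertices
WELD_DECIMALS = 6


class MeshParseError(ValueError):
    """Raised when a mesh file cannot be parsed."""


class Measure(str, enum.Enum):
    """The six curvature measures."""

    KMIN = "kmin"
    KMAX = "kmax"
    MC = "MC"  # mean curvature H
    GC = "GC"  # Gaussian curvature K
    SI = "SI"  # shape index
    CU = "CU"  # curvedness

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CurveRole(str, enum.Enum):
    MARGIN = "margin"
    APICAL = "apical"
    MESIAL_LINE_ANGLE = "mesial_line_angle"
    DISTAL_LINE_ANGLE = "distal_line_angle"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _area_weighted_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Vertex normals as the normalized sum of incident face cross products.

    The face cross product equals twice the face area times the unit face
    normal, so summing it per vertex is an area-weighted average.
    """
    v = vertices
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    norm = np.linalg.norm(normals, axis=1)
    bad = norm < 1e-300
    norm[bad] = 1.0
    normals = normals / norm[:, None]
    # isolated / degenerate vertices get an arbitrary unit normal
    normals[bad] = (0.0, 0.0, 1.0)
    return normals


@dataclass
class TriangleMesh:
    """A triangle surface mesh in millimetres.

    ``vertex_normals`` are unit outward normals; if not supplied they are
    computed area-weighted from consistently wound faces.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int
    vertex_normals: np.ndarray | None = None
    units: str = "mm"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if len(self.vertices) == 0:
            raise MeshParseError("empty mesh: no vertices")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        degen = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 2] == self.faces[:, 0])
        )
        if degen.any():
            raise ValueError("degenerate faces present; weld/clean the mesh first")
        if self.vertex_normals is None:
            self.vertex_normals = _area_weighted_vertex_normals(self.vertices, self.faces)
        else:
            self.vertex_normals = np.ascontiguousarray(self.vertex_normals, dtype=np.float64)
            if self.vertex_normals.shape != self.vertices.shape:
                raise ValueError("vertex_normals shape mismatch")
            err = np.abs(np.linalg.norm(self.vertex_normals, axis=1) - 1.0)
            if err.max() > 1e-9:
                raise ValueError("vertex_normals must be unit length (within 1e-9)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        v = self.vertices
        fn = np.cross(
            v[self.faces[:, 1]] - v[self.faces[:, 0]],
            v[self.faces[:, 2]] - v[self.faces[:, 0]],
        )
        return float(0.5 * np.linalg.norm(fn, axis=1).sum())

    def flipped(self) -> "TriangleMesh":
        """Reverse face winding and normals."""
        return TriangleMesh(
            self.vertices.copy(),
            self.faces[:, ::-1].copy(),
            -self.vertex_normals,
            units=self.units,
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices,
            faces=self.faces,
            vertex_normals=self.vertex_normals,
            process=False,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Apply a rigid motion ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriangleMesh(
            self.vertices @ R.T + t,
            self.faces.copy(),
            self.vertex_normals @ R.T,
            units=self.units,
        )

    def scaled(self, s: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * s, self.faces.copy(), self.vertex_normals, units=self.units)


@dataclass
class ScalarField:
    """One real value per mesh vertex, tagged with measure and diameter."""

    values: np.ndarray
    measure: Measure
    diameter_mm: float
    mesh_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.measure = Measure(self.measure)
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be > 0")
        if self.measure is Measure.SI:
            finite = np.isfinite(self.values)
            if not finite.all():
                raise ValueError("SI field has non-finite values")
            if self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError("SI values must lie in [-1, 1]")
        if self.measure is Measure.CU and self.values.min() < -1e-12:
            raise ValueError("CU values must be non-negative")

    @property
    def name(self) -> str:
        return field_property_name(self.measure, self.diameter_mm)


@dataclass
class LandmarkCurve:
    """Ordered 3D polyline (mm) with an anatomical role."""

    points: np.ndarray  # (k, 3)
    role: CurveRole
    closed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.role = CurveRole(self.role)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (k, 3)")
        if len(self.points) < 2:
            raise ValueError("a landmark curve needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if (seg == 0).any():
            raise ValueError("consecutive curve points must be distinct")

    def length(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# mesh reading / writing


def _weld(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Merge vertices equal after rounding to 1e-6 mm; drop degenerate faces."""
    key = np.round(vertices, WELD_DECIMALS)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_index = rank[inverse]  # old vertex -> new vertex, in first-seen order
    new_vertices = vertices[np.sort(first)]
    new_faces = new_index[faces]
    degen = (
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 2] == new_faces[:, 0])
    )
    # collinear (zero-area) but index-distinct faces are dropped as well
    v = new_vertices
    cross = np.cross(
        v[new_faces[:, 1]] - v[new_faces[:, 0]],
        v[new_faces[:, 2]] - v[new_faces[:, 0]],
    )
    zero_area = np.linalg.norm(cross, axis=1) < 1e-12
    drop = degen | zero_area
    return new_vertices, new_faces[~drop], int(drop.sum())


def _is_closed(faces: np.ndarray) -> bool:
    e = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool((counts == 2).all())


def _orient_outward(mesh: TriangleMesh) -> TriangleMesh:
    """Flip the whole mesh if normals point inward by centroid majority vote.

    The vote is meaningful only for a closed shell enclosing its centroid;
    an open sheet (the usual intraoral scan) keeps the stored winding as
    authoritative, with the explicit flip flag as the override.
    """
    if not _is_closed(mesh.faces):
        return mesh
    centroid = mesh.vertices.mean(axis=0)
    score = np.einsum("ij,ij->i", mesh.vertex_normals, mesh.vertices - centroid)
    if np.mean(np.sign(score)) < 0:
        return mesh.flipped()
    return mesh


def read_mesh(
    path: str | Path,
    fmt: str | None = None,
    orient: bool = True,
    flip_normals: bool = False,
) -> TriangleMesh:
    """Read an STL or PLY mesh into a :class:`TriangleMesh`.

    STL files carry no connectivity: duplicate vertices are welded by exact
    match after rounding to 1e-6 mm and degenerate facets are dropped with a
    logged warning.  Normals are recomputed area-weighted and, when
    ``orient`` is true, flipped outward by majority vote against the mesh
    centroid (``flip_normals`` inverts the result for inside-out scans).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r} (stl or ply)")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise MeshParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise MeshParseError(f"{path}: empty mesh")
    n_before = len(faces)
    vertices, faces, dropped = _weld(vertices, faces)
    if dropped:
        log.warning("%s: dropped %d degenerate facet(s) (%d -> %d)", path, dropped, n_before, len(faces))
    if len(faces) == 0:
        raise MeshParseError(f"{path}: no non-degenerate faces")
    mesh = TriangleMesh(vertices, faces)
    if orient:
        mesh = _orient_outward(mesh)
    if flip_normals:
        mesh = mesh.flipped()
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write STL or PLY (by suffix) without scalar fields."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    mesh.to_trimesh().export(str(path), file_type=fmt)


def field_property_name(measure: Measure, diameter_mm: float) -> str:
    """PLY property name for a field, e.g. ``kmin_d2.0``."""
    return f"{Measure(measure).value}_d{float(diameter_mm)}"


_FIELD_RE = re.compile(r"^(kmin|kmax|MC|GC|SI|CU)_d([0-9.]+)$")


def parse_field_property_name(name: str) -> tuple[Measure, float] | None:
    m = _FIELD_RE.match(name)
    if not m:
        return None
    return Measure(m.group(1)), float(m.group(2))


def write_ply_with_fields(
    mesh: TriangleMesh,
    fields: list[ScalarField],
    path: str | Path,
    colors: np.ndarray | None = None,
    ascii: bool = False,
) -> None:
    """Write a PLY whose vertex element carries one float property per field.

    Property names encode measure and diameter (``kmin_d2.0``); values are
    stored as float32, the native precision of PLY scalar payloads.
    """
    names = set()
    for f in fields:
        if len(f.values) != mesh.n_vertices:
            raise ValueError(
                f"field {f.name}: length {len(f.values)} != vertex count {mesh.n_vertices}"
            )
        if f.name in names:
            raise ValueError(f"duplicate field {f.name}")
        names.add(f.name)
    tm = mesh.to_trimesh()
    for f in fields:
        tm.vertex_attributes[f.name] = f.values.astype(np.float32)
    if colors is not None:
        colors = np.asarray(colors)
        if colors.shape[0] != mesh.n_vertices:
            raise ValueError("colors length mismatch")
        tm.visual.vertex_colors = colors
    data = trimesh.exchange.ply.export_ply(tm, encoding="ascii" if ascii else "binary")
    Path(path).write_bytes(data)


def read_ply_with_fields(path: str | Path) -> tuple[TriangleMesh, list[ScalarField]]:
    """Read back a PLY written by :func:`write_ply_with_fields`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(str(path), file_type="ply", process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001
        raise MeshParseError(f"cannot parse {path} as ply: {exc}") from exc
    mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    fields: list[ScalarField] = []
    raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is not None and getattr(raw, "dtype", None) is not None and raw.dtype.names:
        for name in raw.dtype.names:
            parsed = parse_field_property_name(name)
            if parsed is None:
                continue
            measure, diameter = parsed
            fields.append(
                ScalarField(np.asarray(raw[name], dtype=np.float64).ravel(), measure, diameter)
            )
    return mesh, fields


# ---------------------------------------------------------------------------
# landmark curves

_ROLE_PATTERNS = [
    (re.compile(r"margin", re.I), CurveRole.MARGIN),
    (re.compile(r"apical", re.I), CurveRole.APICAL),
    (re.compile(r"mesial", re.I), CurveRole.MESIAL_LINE_ANGLE),
    (re.compile(r"distal", re.I), CurveRole.DISTAL_LINE_ANGLE),
]


def _role_from_filename(path: Path) -> CurveRole:
    for pat, role in _ROLE_PATTERNS:
        if pat.search(path.stem):
            return role
    raise ValueError(
        f"cannot infer curve role from filename {path.name!r}; pass role= explicitly"
    )


def read_landmark_csv(
    path: str | Path,
    role: CurveRole | str | None = None,
    closed: bool = False,
) -> LandmarkCurve:
    """Read an x,y,z CSV polyline (header optional, mm units)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: cannot read CSV: {exc}") from exc
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns x,y,z, got {df.shape[1]}")
    df = df.iloc[:, :3]
    start = 0
    # optional header row
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        start = 1
    body = df.iloc[start:]
    try:
        pts = body.astype(float).to_numpy()
    except (ValueError, TypeError):
        for i, (_, row) in enumerate(body.iterrows(), start=start + 1):
            try:
                row.astype(float)
            except (ValueError, TypeError):
                raise ValueError(f"{path}: non-numeric value in row {i}") from None
        raise
    if len(pts) < 2:
        raise ValueError(f"{path}: a curve needs at least 2 points, got {len(pts)}")
    role = CurveRole(role) if role is not None else _role_from_filename(path)
    return LandmarkCurve(pts, role=role, closed=closed, label=path.stem)


def write_landmark_csv(curve: LandmarkCurve, path: str | Path) -> None:
    pd.DataFrame(curve.points, columns=["x", "y", "z"]).to_csv(Path(path), index=False)
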