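"""Synthetic surfaces with analytic curvature, and a gingiva phantom.

Every downstream module is testable without scanner data:

* :func:`analytic_surface` builds plane / sphere / cylinder / torus / saddle
  meshes together with a callable returning the exact principal curvatures
  at any surface point (convex-outward-positive convention).

* :func:`generate_phantom` builds a flattened dental-arch phantom: a flat
  "alveolar" base carrying a scalloped gingival margin, one rounded bulge
  per tooth on the central gingiva (the margin roll) and one papilla bulge
  per interdental gap.  Each bulge is an axisymmetric two-arc profile —
  a spherical cap core with a tangent concave rounding back to the base —
  so inside the core both principal curvatures equal exactly 1/radius:
  ``central_ridge_radius_mm`` pins the central kmin ground truth and
  ``interdental_bulge_radius_mm`` the papilla mean-curvature ground truth.
  The bundle ships the margin and line-angle landmark curves, per-vertex
  ground-truth zone labels, and the analytic truth values.

* :func:`simulate_rescan` emulates a second acquisition: Gaussian noise
  along vertex normals, one boundary-pinned Laplacian smoothing pass, and a
  random-offset vertex-clustering remesh so the rescan has different
  connectivity, as real rescans do.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh_io import (
    CurveRole,
    LandmarkCurve,
    TriangleMesh,
    write_landmark_csv,
    write_ply_with_fields,
)

__all__ = [
    "analytic_surface",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "simulate_rescan",
    "write_phantom_bundle",
]


# ---------------------------------------------------------------------------
# grid helper


def _grid_mesh(xs: np.ndarray, ys: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated height-field grid; winding gives +z-ish normals."""
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.asarray(z, dtype=float).ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    q = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 4)
    F = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])
    return V, F


def _graph_curvatures(fx, fy, fxx, fxy, fyy):
    """Exact principal curvatures of z = f(x, y), convex-outward-positive
    with the upward (+z-ish) normal."""
    w2 = 1.0 + fx * fx + fy * fy
    w = np.sqrt(w2)
    K = (fxx * fyy - fxy * fxy) / (w2 * w2)
    H = ((1.0 + fy * fy) * fxx - 2.0 * fx * fy * fxy + (1.0 + fx * fx) * fyy) / (2.0 * w2 * w)
    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    # graph-sign k = H +/- disc; flip for convex-outward-positive
    return -(H + disc), -(H - disc)  # kmin, kmax


# ---------------------------------------------------------------------------
# analytic fixtures


def analytic_surface(kind: str, resolution: float = 0.2, **params):
    """Analytic test surface plus its exact-curvature oracle.

    Returns ``(mesh, curvature_fn)`` where ``curvature_fn(points)`` gives
    per-point ``(kmin, kmax)`` in 1/mm, convex outward positive.

    kinds and size params (mm):
      plane    — size (default 10)
      sphere   — radius (10); resolution sets icosphere subdivisions
      cylinder — radius (5), length (20); an open tube without caps
      torus    — major_radius (10), minor_radius (2)
      saddle   — size (10): z = (x^2 - y^2) / 2
    """
    if not resolution > 0:
        raise ValueError("resolution must be > 0")

    if kind == "plane":
        size = float(params.get("size", 10.0))
        _check_res(resolution, size)
        xs = np.arange(0.0, size + resolution / 2, resolution)
        V, F = _grid_mesh(xs, xs, np.zeros((len(xs), len(xs))))
        mesh = TriangleMesh(V, F)

        def fn(points):
            n = len(np.atleast_2d(points))
            return np.zeros(n), np.zeros(n)

        return mesh, fn

    if kind == "sphere":
        radius = float(params.get("radius", 10.0))
        _check_res(resolution, radius)
        # choose subdivisions so the mean edge is about the resolution
        sub = int(np.clip(np.ceil(np.log2(radius / resolution)) - 1, 2, 7))
        sub = int(params.get("subdivisions", sub))
        ico = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
        mesh = TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))

        def fn(points):
            n = len(np.atleast_2d(points))
            k = np.full(n, 1.0 / radius)
            return k, k.copy()

        return mesh, fn

    if kind == "cylinder":
        radius = float(params.get("radius", 5.0))
        length = float(params.get("length", 20.0))
        _check_res(resolution, radius)
        th = np.arange(0.0, np.pi + 1e-12, resolution / radius)
        ys = np.arange(0.0, length + resolution / 2, resolution)
        TH, Y = np.meshgrid(th, ys, indexing="ij")
        V = np.column_stack(
            [radius * np.sin(TH).ravel(), Y.ravel(), radius * np.cos(TH).ravel()]
        )
        idx = np.arange(len(th) * len(ys)).reshape(len(th), len(ys))
        q = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 4)
        F = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])
        mesh = TriangleMesh(V, F)

        def fn(points):
            n = len(np.atleast_2d(points))
            return np.zeros(n), np.full(n, 1.0 / radius)

        return mesh, fn

    if kind == "torus":
        R = float(params.get("major_radius", 10.0))
        r = float(params.get("minor_radius", 2.0))
        _check_res(resolution, r)
        minor_sections = max(16, int(np.ceil(2 * np.pi * r / resolution)))
        major_sections = max(32, int(np.ceil(2 * np.pi * R / resolution)))
        tor = trimesh.creation.torus(
            major_radius=R,
            minor_radius=r,
            major_sections=major_sections,
            minor_sections=minor_sections,
        )
        tm = TriangleMesh(np.asarray(tor.vertices), np.asarray(tor.faces))
        # guarantee outward orientation regardless of generator winding
        p = tm.vertices
        rho = np.hypot(p[:, 0], p[:, 1])
        out_dir = np.column_stack([p[:, 0] * (1 - R / rho), p[:, 1] * (1 - R / rho), p[:, 2]])
        out_dir /= np.linalg.norm(out_dir, axis=1)[:, None]
        if np.mean(np.einsum("ij,ij->i", tm.vertex_normals, out_dir)) < 0:
            tm = tm.flipped()

        def fn(points):
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            rho = np.hypot(pts[:, 0], pts[:, 1])
            cos_t = np.clip((rho - R) / r, -1.0, 1.0)
            k_tube = np.full(len(pts), 1.0 / r)
            k_ring = cos_t / (R + r * cos_t)
            return np.minimum(k_tube, k_ring), np.maximum(k_tube, k_ring)

        return tm, fn

    if kind == "saddle":
        size = float(params.get("size", 10.0))
        _check_res(resolution, size)
        xs = np.arange(-size / 2, size / 2 + resolution / 2, resolution)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        V, F = _grid_mesh(xs, xs, (X * X - Y * Y) / 2.0)
        mesh = TriangleMesh(V, F)

        def fn(points):
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            x, y = pts[:, 0], pts[:, 1]
            return _graph_curvatures(x, -y, 1.0, 0.0, -1.0)

        return mesh, fn

    raise ValueError(f"unknown surface kind {kind!r}")


def _check_res(resolution: float, feature: float) -> None:
    if feature / resolution < 8:
        raise ValueError(
            f"resolution {resolution} mm too coarse for feature size {feature} mm "
            "(need at least 8 vertices across)"
        )


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomSpec:
    """Parameters of the dental-arch gingiva phantom (all lengths in mm).

    The phantom is a flattened buccal view: x runs mesio-distally along the
    arch, y corono-apically (coronal = +y, so the apical direction is -y),
    z is the outward surface height.
    """

    n_teeth: int = 10
    tooth_spacing_mm: float = 7.0  # tooth width + gap
    gap_mm: float = 2.0
    central_ridge_radius_mm: float = 3.0  # kmin ground truth 1/r on central bulge core
    interdental_bulge_radius_mm: float = 5.0  # MC ground truth 1/r on papilla core
    central_bulge_extent_mm: float = 2.0  # lateral footprint radius of the bulge
    interdental_bulge_extent_mm: float = 1.5
    scallop_amplitude_mm: float = 1.0  # margin height profile
    bulge_depth_mm: float = 1.5  # bulge centre below the local margin
    mesh_resolution_mm: float = 0.15
    noise_sd_mm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_teeth < 1:
            raise ValueError("n_teeth must be >= 1")
        for name in ("central_ridge_radius_mm", "interdental_bulge_radius_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.gap_mm < self.tooth_spacing_mm:
            raise ValueError("need 0 < gap_mm < tooth_spacing_mm")
        min_radius = min(self.central_ridge_radius_mm, self.interdental_bulge_radius_mm)
        if not self.mesh_resolution_mm < min_radius / 5:
            raise ValueError("mesh_resolution_mm must be below min bulge radius / 5")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        w = self.tooth_width_mm
        if 2 * self.central_bulge_extent_mm > w:
            raise ValueError("central bulge wider than the tooth (overlapping bulges)")
        if self.central_bulge_extent_mm + self.interdental_bulge_extent_mm > (w + self.gap_mm) / 2:
            raise ValueError("central and interdental bulges overlap (teeth too close)")
        for ext, r in (
            (self.central_bulge_extent_mm, self.central_ridge_radius_mm),
            (self.interdental_bulge_extent_mm, self.interdental_bulge_radius_mm),
        ):
            if ext >= 2 * r:
                raise ValueError("bulge extent must be below twice its radius")

    @property
    def tooth_width_mm(self) -> float:
        return self.tooth_spacing_mm - self.gap_mm

    @property
    def arch_length_mm(self) -> float:
        return self.n_teeth * self.tooth_width_mm + (self.n_teeth - 1) * self.gap_mm


def _two_arc_bump(rho: np.ndarray, radius: float, extent: float) -> np.ndarray:
    """Axisymmetric bump: spherical cap core + tangent concave rounding.

    Both arcs have the given radius and meet with matched slope at half the
    extent, so the profile is C^1, exactly spherical (curvature 1/radius in
    every direction) for rho <= extent/2, and flat beyond ``extent``.
    """
    rho = np.asarray(rho, dtype=float)
    rho_m = extent / 2.0
    cos_m = np.sqrt(1.0 - (rho_m / radius) ** 2)
    z = np.zeros_like(rho)
    core = rho <= rho_m
    z[core] = 2.0 * radius * (1.0 - cos_m) - radius + np.sqrt(radius**2 - rho[core] ** 2)
    ring = (~core) & (rho < extent)
    z[ring] = radius - np.sqrt(radius**2 - (extent - rho[ring]) ** 2)
    return z


@dataclass
class PhantomBundle:
    """Everything :func:`generate_phantom` knows about its own output."""

    spec: PhantomSpec
    mesh: TriangleMesh
    margin: LandmarkCurve
    line_angle_pairs: list  # per tooth: (mesial LandmarkCurve, distal LandmarkCurve)
    tooth_labels: list
    apical_direction: np.ndarray  # (3,) unit, = -y
    zone_labels: np.ndarray  # per-vertex: "", "central:T01", "interdental:T01-T02"
    truth_apical: LandmarkCurve  # arc-length-integrated apical band boundary
    truth: dict  # analytic ground-truth values

    @property
    def band_mask(self) -> np.ndarray:
        return self.zone_labels != ""


class _PhantomField:
    """Analytic height field of the phantom and helpers on it."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        w, g = spec.tooth_width_mm, spec.gap_mm
        self.tooth_centers = np.array(
            [i * (w + g) + w / 2 for i in range(spec.n_teeth)]
        )
        self.tooth_edges = [(i * (w + g), i * (w + g) + w) for i in range(spec.n_teeth)]
        self.gap_centers = np.array(
            [i * (w + g) + w + g / 2 for i in range(spec.n_teeth - 1)]
        )

    def margin_y(self, x: np.ndarray) -> np.ndarray:
        """Scalloped margin height: coronal bulge over each tooth centre."""
        x = np.asarray(x, dtype=float)
        w = self.spec.tooth_width_mm
        y = np.zeros_like(x)
        for xc in self.tooth_centers:
            t = (x - xc) / (w / 2.0)
            inside = np.abs(t) < 1.0
            y[inside] += self.spec.scallop_amplitude_mm * np.cos(np.pi * t[inside] / 2.0) ** 2
        return y

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        s = self.spec
        z = np.zeros(np.broadcast(x, y).shape)
        depth = s.bulge_depth_mm
        for xc in self.tooth_centers:
            yc = s.scallop_amplitude_mm - depth  # margin_y at tooth centre minus depth
            rho = np.hypot(x - xc, y - yc)
            z += _two_arc_bump(rho, s.central_ridge_radius_mm, s.central_bulge_extent_mm)
        for xg in self.gap_centers:
            yg = 0.0 - depth  # margin is at the base level in the gaps
            rho = np.hypot(x - xg, y - yg)
            z += _two_arc_bump(rho, s.interdental_bulge_radius_mm, s.interdental_bulge_extent_mm)
        return z

    def apical_boundary_y(
        self,
        xs: np.ndarray,
        length: float,
        y_bot: float,
        dy: float = 0.01,
    ) -> np.ndarray:
        """y reached by walking ``length`` mm apically along each column x=const.

        Exact on-surface arc length, integrated on a fine grid: the oracle
        for the band's apical boundary, independent of any surface-marching
        implementation.
        """
        xs = np.asarray(xs, dtype=float)
        y_start = self.margin_y(xs)
        y_hi = float(y_start.max())
        ygrid = np.arange(y_hi, y_bot - dy, -dy)  # descending
        X, Y = np.meshgrid(xs, ygrid, indexing="ij")
        Z = self.height(X, Y)
        dz = np.diff(Z, axis=1)
        ds = np.sqrt(dy * dy + dz * dz)  # (nx, ny-1), segment i -> i+1 going down
        S = np.concatenate([np.zeros((len(xs), 1)), np.cumsum(ds, axis=1)], axis=1)
        # arc position of each column's margin start (linear within a cell)
        i0 = np.clip(np.searchsorted(-ygrid, -y_start), 0, len(ygrid) - 2)
        frac0 = (ygrid[i0] - y_start) / dy
        rows = np.arange(len(xs))
        s0 = S[rows, i0] + frac0 * ds[rows, np.minimum(i0, ds.shape[1] - 1)]
        target = s0 + length
        out = np.empty(len(xs))
        for j in range(len(xs)):
            i = int(np.searchsorted(S[j], target[j]))
            i = min(max(i, 1), S.shape[1] - 1)
            frac = (target[j] - S[j, i - 1]) / (S[j, i] - S[j, i - 1])
            out[j] = ygrid[i - 1] - frac * dy
        return out


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Deterministic gingiva phantom with landmark curves and ground truth."""
    field = _PhantomField(spec)
    s = spec
    res = s.mesh_resolution_mm
    y_top = s.scallop_amplitude_mm + 0.8
    y_bot = -(3.0 + 1.6)
    xs = np.linspace(0.0, s.arch_length_mm, int(round(s.arch_length_mm / res)) + 1)
    ys = np.linspace(y_bot, y_top, int(round((y_top - y_bot) / res)) + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = field.height(X, Y)
    V, F = _grid_mesh(xs, ys, Z)
    mesh = TriangleMesh(V, F)

    # landmark curves
    mx = np.arange(0.0, s.arch_length_mm + 1e-9, 0.1)
    my = field.margin_y(mx)
    margin = LandmarkCurve(
        np.column_stack([mx, my, field.height(mx, my)]), role=CurveRole.MARGIN, label="margin"
    )
    la_y = np.arange(y_bot + 0.2, y_top - 0.2, 0.4)
    pairs = []
    tooth_labels = [f"T{i + 1:02d}" for i in range(s.n_teeth)]
    for i, (x_m, x_d) in enumerate(field.tooth_edges):
        curves = []
        for x_e, role in ((x_m, CurveRole.MESIAL_LINE_ANGLE), (x_d, CurveRole.DISTAL_LINE_ANGLE)):
            pts = np.column_stack([np.full_like(la_y, x_e), la_y, field.height(x_e, la_y)])
            curves.append(LandmarkCurve(pts, role=role, label=f"{role.value}_{tooth_labels[i]}"))
        pairs.append(tuple(curves))

    apical = np.array([0.0, -1.0, 0.0])

    # ground-truth apical boundary: exact arc-length integration per column
    ty = field.apical_boundary_y(mx, 3.0, y_bot)
    truth_apical = LandmarkCurve(
        np.column_stack([mx, ty, field.height(mx, ty)]), role=CurveRole.APICAL, label="truth_apical"
    )

    # per-vertex zone labels: closest-point band rule against the analytic
    # margin and the integrated apical boundary, split by tooth x-intervals
    from .roi import _closest_on_polyline  # geometry utility, not the ROI algorithm

    m_pts, _ = _closest_on_polyline(V, margin.points)
    a_pts, _ = _closest_on_polyline(V, truth_apical.points)
    in_band = ((V - m_pts) @ apical >= -1e-9) & ((V - a_pts) @ apical <= 1e-9)
    labels = np.full(len(V), "", dtype=object)
    vx = V[:, 0]
    for i, (x_m, x_d) in enumerate(field.tooth_edges):
        sel = in_band & (vx >= x_m) & (vx <= x_d)
        labels[sel] = f"central:{tooth_labels[i]}"
    for j in range(s.n_teeth - 1):
        x_lo = field.tooth_edges[j][1]
        x_hi = field.tooth_edges[j + 1][0]
        sel = in_band & (vx > x_lo) & (vx < x_hi)
        labels[sel] = f"interdental:{tooth_labels[j]}-{tooth_labels[j + 1]}"

    truth = {
        "central_kmin": 1.0 / s.central_ridge_radius_mm,
        "central_core_radius_mm": s.central_bulge_extent_mm / 2.0,
        "interdental_mc": 1.0 / s.interdental_bulge_radius_mm,
        "interdental_core_radius_mm": s.interdental_bulge_extent_mm / 2.0,
        "band_offset_mm": 3.0,
        "n_central_zones": s.n_teeth,
        "n_interdental_zones": s.n_teeth - 1,
    }
    return PhantomBundle(
        spec=spec,
        mesh=mesh,
        margin=margin,
        line_angle_pairs=pairs,
        tooth_labels=tooth_labels,
        apical_direction=apical,
        zone_labels=labels.astype(str),
        truth_apical=truth_apical,
        truth=truth,
    )


def write_phantom_bundle(bundle: PhantomBundle, out_dir: str | Path) -> None:
    """Write mesh.ply, margin.csv, line_angles_*.csv, labels.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ply_with_fields(bundle.mesh, [], out / "mesh.ply")
    write_landmark_csv(bundle.margin, out / "margin.csv")
    for label, (mesial, distal) in zip(bundle.tooth_labels, bundle.line_angle_pairs):
        write_landmark_csv(mesial, out / f"line_angles_mesial_{label}.csv")
        write_landmark_csv(distal, out / f"line_angles_distal_{label}.csv")
    pd.DataFrame(
        {"vertex_index": np.arange(bundle.mesh.n_vertices), "zone": bundle.zone_labels}
    ).to_csv(out / "labels.csv", index=False)
    meta = dict(bundle.truth)
    meta["spec"] = asdict(bundle.spec)
    meta["apical_direction"] = bundle.apical_direction.tolist()
    (out / "truth.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# rescan simulation


def _boundary_vertices(faces: np.ndarray, n_vertices: int) -> np.ndarray:
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    mask = np.zeros(n_vertices, dtype=bool)
    mask[uniq[counts == 1].ravel()] = True
    return mask


def _laplacian_pass(vertices: np.ndarray, faces: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """One uniform-weight smoothing step; boundary vertices stay pinned."""
    n = len(vertices)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.concatenate([e, e[:, ::-1]])
    e = np.unique(e, axis=0)
    acc = np.zeros_like(vertices)
    cnt = np.zeros(n)
    np.add.at(acc, e[:, 0], vertices[e[:, 1]])
    np.add.at(cnt, e[:, 0], 1.0)
    cnt[cnt == 0] = 1.0
    mean = acc / cnt[:, None]
    out = vertices + lam * (mean - vertices)
    pinned = _boundary_vertices(faces, n)
    out[pinned] = vertices[pinned]
    return out


def _cluster_remesh(
    vertices: np.ndarray, faces: np.ndarray, cell: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-clustering decimation on a randomly offset grid."""
    offset = rng.uniform(0.0, cell, size=3)
    key = np.floor((vertices - offset) / cell).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    k = first.shape[0]
    new_v = np.zeros((k, 3))
    cnt = np.zeros(k)
    np.add.at(new_v, inverse, vertices)
    np.add.at(cnt, inverse, 1.0)
    new_v /= cnt[:, None]
    new_f = inverse[faces]
    degen = (
        (new_f[:, 0] == new_f[:, 1])
        | (new_f[:, 1] == new_f[:, 2])
        | (new_f[:, 2] == new_f[:, 0])
    )
    new_f = new_f[~degen]
    # drop duplicated faces (same vertex triple, any order)
    trip = np.sort(new_f, axis=1)
    _, keep = np.unique(trip, axis=0, return_index=True)
    new_f = new_f[np.sort(keep)]
    # drop unreferenced vertices
    used = np.unique(new_f)
    remap = np.full(k, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return new_v[used], remap[new_f]


def simulate_rescan(
    mesh: TriangleMesh,
    noise_sd_mm: float,
    seed: int,
    remesh: bool = True,
    smooth: bool = True,
) -> TriangleMesh:
    """A second, independent acquisition of the same surface.

    Gaussian displacement along vertex normals (sd = ``noise_sd_mm``), one
    Laplacian smoothing pass, then a random-offset vertex-clustering remesh
    at the original mean edge length, so the output connectivity differs
    from the input.  Deterministic given the seed.  With
    ``noise_sd_mm=0, remesh=False, smooth=False`` the mesh is returned
    unchanged (a copy).
    """
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    v = mesh.vertices.copy()
    f = mesh.faces.copy()
    if noise_sd_mm > 0:
        v = v + rng.normal(0.0, noise_sd_mm, len(v))[:, None] * mesh.vertex_normals
    if smooth:
        v = _laplacian_pass(v, f)
    if remesh:
        edges = np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1)
        cell = float(edges.mean())
        sub_v, sub_f = trimesh.remesh.subdivide(v, f)
        v, f = _cluster_remesh(sub_v, sub_f, cell, rng)
    return TriangleMesh(v, f)
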