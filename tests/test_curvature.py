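"""Curvature engine: neighbourhoods, quadric fits, Weingarten eigenstructure,
and whole-mesh estimation against analytic surfaces."""

from __future__ import annotations

import numpy as np
import pytest

from gingshape.curvature import (
    LocalQuadric,
    collect_neighborhood,
    estimate_curvature,
    fit_local_quadric,
    principal_from_quadric,
)
from gingshape.mesh_io import TriangleMesh
from gingshape.synthetic import analytic_surface


def _grid_plane(spacing=0.1, n=21):
    xs = np.arange(n) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    idx = np.arange(n * n).reshape(n, n)
    q = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 4)
    F = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])
    return TriangleMesh(V, F)


IDENTITY_FRAME = np.eye(3)


class TestNeighborhood:
    def test_matches_euclidean_ball_on_grid(self):
        mesh = _grid_plane(spacing=0.1, n=21)
        seed = 210  # interior vertex
        nbrs = collect_neighborhood(mesh, seed, diameter_mm=0.5)
        d = np.linalg.norm(mesh.vertices - mesh.vertices[seed], axis=1)
        brute = np.flatnonzero(d <= 0.25)
        assert np.array_equal(nbrs, np.sort(brute))

    def test_tiny_diameter_gives_singleton(self):
        mesh = _grid_plane(spacing=0.1, n=5)
        assert list(collect_neighborhood(mesh, 12, diameter_mm=0.05)) == [12]

    def test_never_crosses_between_disconnected_sheets(self):
        a = _grid_plane(spacing=0.1, n=9)
        off = a.vertices.copy()
        off[:, 2] += 0.1  # parallel sheet 0.1 mm away, no shared edges
        V = np.vstack([a.vertices, off])
        F = np.vstack([a.faces, a.faces + a.n_vertices])
        mesh = TriangleMesh(V, F)
        nbrs = collect_neighborhood(mesh, 40, diameter_mm=2.0)
        assert nbrs.max() < a.n_vertices  # only the seed's own sheet
        assert len(nbrs) == a.n_vertices

    def test_requires_positive_diameter(self):
        mesh = _grid_plane(n=5)
        with pytest.raises(ValueError):
            collect_neighborhood(mesh, 0, diameter_mm=0.0)


class TestQuadricFit:
    def _mesh_from_graph(self, f):
        """Height field z = f(x, y) over a small grid; normals +z at centre."""
        xs = np.linspace(-0.5, 0.5, 11)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        V = np.column_stack([X.ravel(), Y.ravel(), f(X, Y).ravel()])
        idx = np.arange(121).reshape(11, 11)
        q = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 4)
        F = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])
        normals = np.tile([0.0, 0.0, 1.0], (121, 1))
        return TriangleMesh(V, F, vertex_normals=normals)

    def test_plane_fits_to_zero(self):
        mesh = self._mesh_from_graph(lambda x, y: 0.0 * x)
        q = fit_local_quadric(mesh, 60, np.arange(121))
        assert np.allclose(q.coeffs, 0.0, atol=1e-9)

    def test_exact_parabola_recovered(self):
        # z = y^2; in the deterministic frame of normal +z, u = -y so z = u^2
        mesh = self._mesh_from_graph(lambda x, y: y**2)
        q = fit_local_quadric(mesh, 60, np.arange(121))
        a, b, c, d, e, f0 = q.coeffs
        assert a == pytest.approx(1.0, abs=1e-9)
        assert np.allclose([b, c, d, e, f0], 0.0, atol=1e-9)

    def test_sphere_cap_curvature(self, rng):
        # neighbours on a radius-5 sphere within a 2 mm cap around the pole
        r = 5.0
        rho = rng.uniform(0.0, 1.0, 80)
        phi = rng.uniform(0, 2 * np.pi, 80)
        x, y = rho * np.cos(phi), rho * np.sin(phi)
        z = np.sqrt(r**2 - rho**2) - r  # pole at origin, sphere below
        V = np.column_stack([np.r_[0.0, x], np.r_[0.0, y], np.r_[0.0, z]])
        F = np.column_stack([np.zeros(79, int), np.arange(1, 80), np.arange(2, 81)])
        normals = np.tile([0.0, 0.0, 1.0], (81, 1))
        mesh = TriangleMesh(V, F, vertex_normals=normals)
        q = fit_local_quadric(mesh, 0, np.arange(81))
        kmin, kmax, _, _ = principal_from_quadric(q)
        # a least-squares quadric over a cap of chord radius c on a sphere of
        # radius r carries a truncation bias of order c^2/(4 r^3) ~ 2e-3 here
        assert abs(kmin) == pytest.approx(1.0 / r, abs=2.5e-3)
        assert abs(kmax) == pytest.approx(1.0 / r, abs=2.5e-3)

    def test_too_few_neighbours_refused(self):
        mesh = self._mesh_from_graph(lambda x, y: 0.0 * x)
        with pytest.raises(ValueError, match="at least 6"):
            fit_local_quadric(mesh, 0, np.arange(5))

    def test_rank_deficient_collinear_flagged(self):
        mesh = self._mesh_from_graph(lambda x, y: 0.0 * x)
        col = np.arange(0, 121, 11)[:8]  # one grid row: collinear
        q = fit_local_quadric(mesh, col[3], col)
        assert q.rank_deficient


class TestPrincipalFromQuadric:
    def _q(self, a, b, c, d=0.0, e=0.0):
        return LocalQuadric(0, IDENTITY_FRAME.copy(), np.array([a, b, c, d, e, 0.0]), 10)

    def test_unit_paraboloid_is_unit_umbilic(self):
        kmin, kmax, _, _ = principal_from_quadric(self._q(0.5, 0.0, 0.5))
        assert kmin == pytest.approx(1.0, abs=1e-12)
        assert kmax == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_case_values_and_directions(self):
        kmin, kmax, dmin, dmax = principal_from_quadric(self._q(1.0, 0.0, -0.5))
        assert kmax == pytest.approx(2.0, abs=1e-12)
        assert kmin == pytest.approx(-1.0, abs=1e-12)
        assert abs(np.dot(dmax, [1, 0, 0])) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.dot(dmin, [0, 1, 0])) == pytest.approx(1.0, abs=1e-9)

    def test_tilted_patch_matches_finite_difference_oracle(self):
        # z = (u^2 + v^2)/2 + u: gradient (1, 0) at the origin
        a, b, c, d, e = 0.5, 0.0, 0.5, 1.0, 0.0
        kmin, kmax, dmin, dmax = principal_from_quadric(self._q(a, b, c, d, e))

        def surf(u, v):
            return np.array([u, v, a * u * u + b * u * v + c * v * v + d * u + e * v])

        h = 1e-5
        Su = (surf(h, 0) - surf(-h, 0)) / (2 * h)
        Sv = (surf(0, h) - surf(0, -h)) / (2 * h)
        Suu = (surf(h, 0) - 2 * surf(0, 0) + surf(-h, 0)) / h**2
        Svv = (surf(0, h) - 2 * surf(0, 0) + surf(0, -h)) / h**2
        Suv = (surf(h, h) - surf(h, -h) - surf(-h, h) + surf(-h, -h)) / (4 * h**2)
        n = np.cross(Su, Sv)
        n /= np.linalg.norm(n)
        I = np.array([[Su @ Su, Su @ Sv], [Su @ Sv, Sv @ Sv]])
        II = np.array([[Suu @ n, Suv @ n], [Suv @ n, Svv @ n]])
        expected = np.sort(np.linalg.eigvals(np.linalg.solve(I, II)).real)
        assert kmin == pytest.approx(expected[0], abs=1e-6)
        assert kmax == pytest.approx(expected[1], abs=1e-6)
        # directions orthogonal in 3D, tangent to the actual (tilted) surface
        assert abs(np.dot(dmin, dmax)) < 1e-9

    def test_umbilic_directions_are_orthonormal_tangent(self):
        _, _, dmin, dmax = principal_from_quadric(self._q(0.5, 0.0, 0.5))
        assert abs(np.dot(dmin, dmax)) < 1e-12
        assert abs(dmin @ [0, 0, 1]) < 1e-12


class TestEstimateCurvature:
    def test_sphere_positive_one_over_r(self):
        mesh, fn = analytic_surface("sphere", radius=10.0, resolution=0.35)
        field = estimate_curvature(mesh, 2.0)
        k_true, _ = fn(mesh.vertices)
        assert np.median(np.abs(field.kmin - k_true)) < 5e-3
        assert np.median(np.abs(field.kmax - k_true)) < 5e-3
        assert np.median(field.kmin) > 0  # convex outward is positive
        assert np.median(field.kmax - field.kmin) < 5e-3  # near-umbilic everywhere

    def test_cylinder_kmax_and_flat_axis(self):
        mesh, _ = analytic_surface("cylinder", radius=5.0, length=20.0, resolution=0.25)
        field = estimate_curvature(mesh, 2.0)
        interior = (mesh.vertices[:, 1] > 2.5) & (mesh.vertices[:, 1] < 17.5)
        assert np.median(field.kmax[interior]) == pytest.approx(0.2, abs=5e-3)
        assert np.median(np.abs(field.kmin[interior])) < 5e-3

    def test_scaling_law(self):
        mesh, _ = analytic_surface("saddle", size=8.0, resolution=0.4)
        f1 = estimate_curvature(mesh, 2.0)
        f2 = estimate_curvature(mesh.scaled(2.0), 4.0)
        # 1e-6 relative, with an absolute floor for numerically zero values
        assert np.allclose(f2.kmin * 2.0, f1.kmin, rtol=1e-6, atol=1e-9)
        assert np.allclose(f2.kmax * 2.0, f1.kmax, rtol=1e-6, atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        mesh, _ = analytic_surface("sphere", radius=10.0, subdivisions=3, resolution=0.7)
        f1 = estimate_curvature(mesh, 2.0)
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        moved = mesh.transformed(R, rng.uniform(-5, 5, 3))
        f2 = estimate_curvature(moved, 2.0)
        assert np.max(np.abs(f1.kmin - f2.kmin)) < 1e-9
        assert np.max(np.abs(f1.kmax - f2.kmax)) < 1e-9
        # directions rotate with the motion (up to sign)
        aligned = np.abs(np.einsum("ij,ij->i", f1.dir_max @ R.T, f2.dir_max))
        assert np.median(aligned[~f1.umbilic]) > 0.999

    def test_direction_invariants_on_torus(self):
        mesh, _ = analytic_surface("torus", major_radius=10.0, minor_radius=2.0, resolution=0.25)
        field = estimate_curvature(mesh, 1.5)
        dots = np.abs(np.einsum("ij,ij->i", field.dir_min, field.dir_max))
        assert dots.max() < 1e-6
        ndots = np.abs(np.einsum("ij,ij->i", field.dir_min, mesh.vertex_normals))
        assert np.percentile(ndots, 99) < 1e-3
        assert np.all(field.kmax >= field.kmin)

    def test_tiny_mesh_refused(self):
        V = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        F = np.array([[0, 1, 2]])
        with pytest.raises(ValueError, match="at least 6"):
            estimate_curvature(TriangleMesh(V, F), 1.0)

    def test_sparse_ball_falls_back_to_rings(self):
        mesh = _grid_plane(spacing=0.2, n=9)
        field = estimate_curvature(mesh, 0.1)  # ball smaller than edges
        assert field.fallback.all()
        assert (field.n_neighbors >= 6).all()
        assert np.allclose(field.kmax, 0.0, atol=1e-9)
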