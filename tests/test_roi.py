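"""Margin-band ROI construction: apical offset marching, band selection,
line-angle splitting, and agreement with phantom ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from gingshape.mesh_io import CurveRole, LandmarkCurve, TriangleMesh
from gingshape.roi import (
    ROISelection,
    build_tooth_rois,
    load_rois_csv,
    offset_margin_apically,
    save_rois_csv,
    select_band,
    split_by_line_angles,
)
from gingshape.synthetic import analytic_surface

APICAL = np.array([0.0, -1.0, 0.0])


def _flat_strip(size=10.0, res=0.2):
    xs = np.arange(0.0, size + res / 2, res)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    idx = np.arange(X.size).reshape(len(xs), len(xs))
    q = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 4)
    F = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])
    return TriangleMesh(V, F)


def _line(y, x0=1.0, x1=9.0, n=41):
    xs = np.linspace(x0, x1, n)
    return LandmarkCurve(
        np.column_stack([xs, np.full(n, float(y)), np.zeros(n)]), role=CurveRole.MARGIN
    )


class TestApicalOffset:
    def test_flat_translation(self):
        mesh = _flat_strip()
        margin = _line(8.0)
        out = offset_margin_apically(mesh, margin, APICAL, offset_mm=3.0)
        assert out.role is CurveRole.APICAL
        assert np.max(np.abs(out.points[:, 1] - 5.0)) < 1e-6
        assert np.max(np.abs(out.points[:, 0] - margin.points[:, 0])) < 1e-6

    def test_zero_offset_is_identity(self):
        mesh = _flat_strip()
        margin = _line(8.0)
        out = offset_margin_apically(mesh, margin, APICAL, offset_mm=0.0)
        assert np.array_equal(out.points, margin.points)

    def test_cylinder_axial_geodesic(self):
        # margin on a circumferential line; the apical march follows the
        # axis, so the unrolled-plane geodesic offset is exactly 3 mm axial
        mesh, _ = analytic_surface("cylinder", radius=8.0, length=12.0, resolution=0.25)
        th = np.linspace(0.4, np.pi - 0.4, 60)
        margin = LandmarkCurve(
            np.column_stack([8 * np.sin(th), np.full(60, 10.0), 8 * np.cos(th)]),
            role=CurveRole.MARGIN,
        )
        out = offset_margin_apically(mesh, margin, APICAL, offset_mm=3.0)
        axial = 10.0 - out.points[:, 1]
        assert np.max(np.abs(axial - 3.0)) < 0.02 * 3.0

    def test_boundary_clamp_warns(self, caplog):
        mesh = _flat_strip(size=10.0)
        margin = _line(2.0)  # only 2 mm of surface left apically
        with caplog.at_level("WARNING"):
            out = offset_margin_apically(mesh, margin, APICAL, offset_mm=3.0)
        assert np.all(out.points[:, 1] < 0.3)  # clamped near the y=0 edge
        assert any("clamp" in rec.message for rec in caplog.records)

    def test_margin_off_surface_rejected(self):
        mesh = _flat_strip()
        bad = LandmarkCurve(
            np.column_stack([np.linspace(1, 9, 10), np.full(10, 8.0), np.full(10, 2.0)]),
            role=CurveRole.MARGIN,
        )
        with pytest.raises(ValueError, match="margin"):
            offset_margin_apically(mesh, bad, APICAL, offset_mm=3.0)


class TestSelectBand:
    def test_flat_strip_coordinate_oracle(self):
        mesh = _flat_strip()
        margin = _line(8.0)
        apical = offset_margin_apically(mesh, margin, APICAL, offset_mm=3.0)
        band = select_band(mesh, margin, apical, APICAL)
        y = mesh.vertices[:, 1]
        oracle = np.flatnonzero((y >= 5.0 - 1e-9) & (y <= 8.0 + 1e-9))
        assert np.array_equal(band.vertex_indices, oracle)

    def test_degenerate_equal_curves_rejected(self):
        mesh = _flat_strip()
        margin = _line(8.0)
        with pytest.raises(ValueError):
            select_band(mesh, margin, _line(8.0), APICAL)

    def test_intersecting_curves_rejected(self):
        mesh = _flat_strip()
        margin = _line(8.0)
        crossing = LandmarkCurve(
            np.column_stack([[1.0, 9.0], [5.0, 9.0], [0.0, 0.0]]).T.reshape(2, 3),
            role=CurveRole.APICAL,
        )
        # build explicitly: from (1,5,0) to (9,9,0) crosses y=8
        crossing = LandmarkCurve(
            np.array([[1.0, 5.0, 0.0], [9.0, 9.0, 0.0]]), role=CurveRole.APICAL
        )
        with pytest.raises(ValueError, match="intersect"):
            select_band(mesh, margin, crossing, APICAL)


class TestSplit:
    def test_flat_strip_cut_lines(self):
        mesh = _flat_strip()
        margin = _line(8.0, x0=0.0, x1=10.0)
        apical = offset_margin_apically(mesh, margin, APICAL, offset_mm=3.0)
        band = select_band(mesh, margin, apical, APICAL)
        cut = lambda x: LandmarkCurve(
            np.column_stack([np.full(11, x), np.linspace(4, 9, 11), np.zeros(11)]),
            role=CurveRole.MESIAL_LINE_ANGLE,
        )
        central, inter = split_by_line_angles(band, mesh, cut(2.0), cut(8.0), APICAL)
        x = mesh.vertices[:, 0]
        in_central = (x[band.vertex_indices] >= 2.0) & (x[band.vertex_indices] <= 8.0)
        assert np.array_equal(central.vertex_indices, np.sort(band.vertex_indices[in_central]))
        # partition contract
        union = np.union1d(central.vertex_indices, inter.vertex_indices)
        assert np.array_equal(union, band.vertex_indices)
        assert len(np.intersect1d(central.vertex_indices, inter.vertex_indices)) == 0

    def test_planes_outside_band_rejected(self):
        mesh = _flat_strip()
        margin = _line(8.0, x0=0.0, x1=10.0)
        apical = offset_margin_apically(mesh, margin, APICAL, offset_mm=3.0)
        band = select_band(mesh, margin, apical, APICAL)
        cut = lambda x: LandmarkCurve(
            np.column_stack([np.full(5, x), np.linspace(4, 9, 5), np.zeros(5)]),
            role=CurveRole.MESIAL_LINE_ANGLE,
        )
        with pytest.raises(ValueError):
            split_by_line_angles(band, mesh, cut(-5.0), cut(-2.0), APICAL)


class TestPhantomAgreement:
    def test_band_and_zone_labels_match_ground_truth(self, phantom4, phantom4_rois):
        band, centrals, inters = phantom4_rois
        pred = np.full(phantom4.mesh.n_vertices, "", dtype=object)
        for r in centrals:
            pred[r.vertex_indices] = f"central:{r.tooth_label}"
        for r in inters:
            pred[r.vertex_indices] = f"interdental:{r.tooth_label}"
        union = phantom4.band_mask | (pred != "")
        agreement = np.mean(np.asarray(pred[union]) == phantom4.zone_labels[union])
        assert agreement >= 0.99

    def test_partition_is_exact(self, phantom4_rois):
        band, centrals, inters = phantom4_rois
        pieces = [r.vertex_indices for r in centrals + inters]
        allv = np.concatenate(pieces)
        assert len(allv) == len(np.unique(allv))  # disjoint
        assert np.array_equal(np.sort(allv), band.vertex_indices)  # covers the band

    def test_counts_match_tooth_layout(self, phantom4, phantom4_rois):
        _, centrals, inters = phantom4_rois
        assert len(centrals) == phantom4.spec.n_teeth
        assert len(inters) == phantom4.spec.n_teeth - 1


def test_roi_csv_round_trip(tmp_path, phantom4_rois):
    _, centrals, inters = phantom4_rois
    path = tmp_path / "rois.csv"
    save_rois_csv(centrals + inters, path)
    back = load_rois_csv(path)
    by_key = {(r.kind, r.tooth_label): r for r in back}
    for r in centrals + inters:
        assert np.array_equal(by_key[(r.kind, r.tooth_label)].vertex_indices, r.vertex_indices)


def test_empty_roi_rejected():
    with pytest.raises(ValueError):
        ROISelection(np.array([], dtype=int), kind="central")
    with pytest.raises(ValueError):
        ROISelection(np.array([1, 2]), kind="bogus")
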