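"""The gingival shape parameter (GS) and per-ROI descriptive statistics.

GS is the 95th percentile of a curvature measure's values inside an ROI.
The band deliberately includes part of the gingival margin line, whose
near-zero curvature pulls the ROI mean toward zero; a high percentile
captures the local maximum shape (the bulge of interest) while discounting
that contamination.  Percentiles use linear interpolation between closest
order statistics, and operate on signed values — under the
convex-outward-positive convention the positive tail is the bulge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curvature import estimate_curvature
from .measures import MEASURES, all_measures
from .mesh_io import Measure, ScalarField, TriangleMesh
from .roi import ROISelection

__all__ = [
    "GSRecord",
    "compute_gs",
    "curvature_fields",
    "gs_table",
    "cohort_summary",
    "GS_TABLE_COLUMNS",
]

DEFAULT_PERCENTILE = 95.0
DEFAULT_MIN_VERTICES = 20

GS_TABLE_COLUMNS = [
    "tooth_label",
    "roi_kind",
    "measure",
    "diameter_mm",
    "n_vertices",
    "gs",
    "mean",
    "sd",
    "p5",
    "median",
    "p95",
]


@dataclass
class GSRecord:
    """One gingival-shape value with its ROI descriptives."""

    roi_kind: str
    tooth_label: str
    measure: Measure
    diameter_mm: float
    gs: float
    n_vertices: int
    mean: float
    sd: float
    p5: float
    median: float
    p95: float


def compute_gs(
    field: ScalarField,
    roi: ROISelection,
    percentile: float = DEFAULT_PERCENTILE,
    min_vertices: int = DEFAULT_MIN_VERTICES,
) -> GSRecord:
    """GS of one scalar field over one ROI.

    ``percentile`` defaults to 95; linear interpolation between order
    statistics.  ROIs below ``min_vertices`` are refused: the percentile of
    a handful of vertices is not a shape statistic.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    idx = roi.vertex_indices
    if idx.max() >= len(field.values):
        raise ValueError("ROI indices exceed field length; field and ROI must share a mesh")
    if len(idx) < min_vertices:
        raise ValueError(
            f"ROI has {len(idx)} vertices (< {min_vertices}); enlarge the ROI or lower the floor"
        )
    vals = field.values[idx]
    return GSRecord(
        roi_kind=roi.kind,
        tooth_label=roi.tooth_label,
        measure=field.measure,
        diameter_mm=field.diameter_mm,
        gs=float(np.percentile(vals, percentile)),
        n_vertices=len(idx),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        p5=float(np.percentile(vals, 5)),
        median=float(np.median(vals)),
        p95=float(np.percentile(vals, 95)),
    )


def curvature_fields(
    mesh: TriangleMesh,
    diameters: list[float] = (0.5, 1.0, 2.0),
    si_orientation: int = 1,
) -> dict[tuple[Measure, float], ScalarField]:
    """All six measures at every requested diameter (6 x len(diameters) fields)."""
    out: dict[tuple[Measure, float], ScalarField] = {}
    for d in diameters:
        pcf = estimate_curvature(mesh, d)
        for measure, f in all_measures(pcf, si_orientation=si_orientation).items():
            out[(measure, float(d))] = f
    return out


def gs_table(
    fields: dict[tuple[Measure, float], ScalarField],
    rois: list[ROISelection],
    measures: list[Measure] = MEASURES,
    diameters: list[float] | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    min_vertices: int = DEFAULT_MIN_VERTICES,
) -> pd.DataFrame:
    """One row per (ROI, measure, diameter).

    ``fields`` is keyed by (measure, diameter) as produced by
    :func:`curvature_fields`; a missing combination raises, naming it.
    """
    if diameters is None:
        diameters = sorted({d for _, d in fields})
    rows = []
    for roi in rois:
        for measure in measures:
            for d in diameters:
                key = (Measure(measure), float(d))
                if key not in fields:
                    raise KeyError(f"no curvature field for measure={key[0]} diameter={key[1]} mm")
                rec = compute_gs(fields[key], roi, percentile=percentile, min_vertices=min_vertices)
                rows.append(
                    {
                        "tooth_label": rec.tooth_label,
                        "roi_kind": rec.roi_kind,
                        "measure": rec.measure.value,
                        "diameter_mm": rec.diameter_mm,
                        "n_vertices": rec.n_vertices,
                        "gs": rec.gs,
                        "mean": rec.mean,
                        "sd": rec.sd,
                        "p5": rec.p5,
                        "median": rec.median,
                        "p95": rec.p95,
                    }
                )
    return pd.DataFrame(rows, columns=GS_TABLE_COLUMNS)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Across-ROI mean and sd of GS per (roi_kind, measure, diameter)."""
    g = table.groupby(["roi_kind", "measure", "diameter_mm"], sort=True)["gs"]
    out = g.agg(gs_mean="mean", gs_sd="std", n_rois="count").reset_index()
    out["gs_sd"] = out["gs_sd"].fillna(0.0)
    return out
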