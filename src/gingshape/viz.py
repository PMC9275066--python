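"""Discrete threshold colour-coding of curvature fields on the margin band.

Curvature is visualised only inside the ROI, with a small number of colour
bins separated by fixed thresholds, so the clinically interesting positive
tail (local maxima, conventionally red) stands out.  Threshold values are
configuration, not constants: no clinically settled defaults exist yet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh_io import ScalarField, TriangleMesh, write_ply_with_fields
from .roi import ROISelection

__all__ = ["DiscreteColorScale", "colorize", "write_colored_ply", "DEFAULT_SCALE"]


@dataclass
class DiscreteColorScale:
    """Strictly increasing thresholds and one more RGB colour than bins.

    A value v falls in bin i = number of thresholds <= v (lower edge
    inclusive, upper edge exclusive).  Vertices outside the ROI get
    ``out_of_band_color``.
    """

    thresholds: np.ndarray
    colors: np.ndarray  # (len(thresholds)+1, 3) uint8
    out_of_band_color: tuple = (200, 200, 200)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float).ravel()
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        if len(self.thresholds) == 0:
            raise ValueError("need at least one threshold")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.colors.shape != (len(self.thresholds) + 1, 3):
            raise ValueError("need exactly one more colour than thresholds")

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.thresholds, np.asarray(values, float), side="right")

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscreteColorScale":
        cfg = json.loads(Path(path).read_text())
        return cls(
            thresholds=cfg["thresholds"],
            colors=cfg["colors"],
            out_of_band_color=tuple(cfg.get("out_of_band_color", (200, 200, 200))),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "thresholds": self.thresholds.tolist(),
                    "colors": self.colors.tolist(),
                    "out_of_band_color": list(self.out_of_band_color),
                },
                indent=2,
            )
        )


#: blue (concave) through green (flat) to red (strong convex maxima)
DEFAULT_SCALE = DiscreteColorScale(
    thresholds=np.array([-0.5, -0.25, -0.05, 0.05, 0.25, 0.5]),
    colors=np.array(
        [
            (40, 40, 180),
            (80, 120, 220),
            (140, 200, 240),
            (120, 200, 120),
            (250, 220, 90),
            (250, 140, 60),
            (220, 40, 40),
        ],
        dtype=np.uint8,
    ),
)


def colorize(
    field: ScalarField,
    roi: ROISelection | None,
    scale: DiscreteColorScale = DEFAULT_SCALE,
) -> np.ndarray:
    """Per-vertex RGB (uint8) for one scalar field, restricted to the ROI.

    A pure function of (value, thresholds): permuting vertices permutes
    colours identically.  ``roi=None`` colours the whole mesh.
    """
    n = len(field.values)
    rgb = np.tile(np.asarray(scale.out_of_band_color, dtype=np.uint8), (n, 1))
    if roi is None:
        idx = np.arange(n)
    else:
        idx = roi.vertex_indices
    rgb[idx] = scale.colors[scale.bin_of(field.values[idx])]
    return rgb


def write_colored_ply(
    mesh: TriangleMesh,
    field: ScalarField,
    roi: ROISelection | None,
    path: str | Path,
    scale: DiscreteColorScale = DEFAULT_SCALE,
) -> None:
    """Colour-coded PLY (uchar red/green/blue vertex properties) plus the
    scalar field itself for downstream tools."""
    write_ply_with_fields(mesh, [field], path, colors=colorize(field, roi, scale))
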