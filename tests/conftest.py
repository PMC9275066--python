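"""Shared fixtures: a small gingiva phantom and derived curvature fields.

Everything is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from gingshape.roi import build_tooth_rois, offset_margin_apically, select_band
from gingshape.shape_stats import curvature_fields
from gingshape.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom4():
    """Four-tooth phantom bundle (deterministic)."""
    return generate_phantom(PhantomSpec(n_teeth=4))


@pytest.fixture(scope="session")
def phantom4_fields(phantom4):
    """Curvature measure fields of the phantom at 1 and 2 mm."""
    return curvature_fields(phantom4.mesh, diameters=(1.0, 2.0))


@pytest.fixture(scope="session")
def phantom4_rois(phantom4):
    """(band, centrals, interdentals) built by the ROI pipeline."""
    b = phantom4
    apical_curve = offset_margin_apically(b.mesh, b.margin, b.apical_direction, 3.0)
    band = select_band(b.mesh, b.margin, apical_curve, b.apical_direction)
    centrals, inters = build_tooth_rois(
        b.mesh, band, b.line_angle_pairs, b.apical_direction, b.tooth_labels
    )
    return band, centrals, inters


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
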