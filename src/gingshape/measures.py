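"""The six curvature measures derived from principal curvatures.

Given per-vertex principal curvatures (kmin, kmax) the toolkit derives:

    mean curvature       H  = (kmax + kmin) / 2          [1/mm]
    Gaussian curvature   K  = kmax * kmin                [1/mm^2]
    shape index          SI = (2/pi) atan((kmin+kmax)/(kmin-kmax))   [-]
    curvedness           CU = sqrt((kmax^2 + kmin^2)/2)  [1/mm]

plus kmin and kmax themselves.  SI classifies local shape on the
cup-saddle-cap continuum and is the only scale-invariant measure; all the
others shrink as the geometry (or the estimation diameter) grows.
"""

from __future__ import annotations

import numpy as np

from .curvature import PrincipalCurvatureField
from .mesh_io import Measure, ScalarField

__all__ = [
    "mean_curvature",
    "gaussian_curvature",
    "shape_index",
    "curvedness",
    "all_measures",
    "MEASURES",
]

MEASURES: tuple[Measure, ...] = (
    Measure.KMIN,
    Measure.KMAX,
    Measure.MC,
    Measure.GC,
    Measure.SI,
    Measure.CU,
)

#: |kmax - kmin| at or below this is treated as an umbilic point for SI
SI_UMBILIC_ATOL = 1e-12


def mean_curvature(kmin, kmax):
    """H = (kmax + kmin) / 2."""
    return (np.asarray(kmax, float) + np.asarray(kmin, float)) / 2.0


def gaussian_curvature(kmin, kmax):
    """K = kmax * kmin."""
    return np.asarray(kmax, float) * np.asarray(kmin, float)


def shape_index(kmin, kmax, orientation: int = 1):
    """SI = (2/pi) * arctan((kmin + kmax) / (kmin - kmax)).

    The formula is 0/0 at umbilic points (kmin == kmax); there SI is set by
    continuity to -sign(H), and to 0 at exact flat points.  ``orientation``
    (+1/-1) flips the sign globally for pipelines using the opposite
    curvature sign convention.
    """
    kmin = np.asarray(kmin, dtype=float)
    kmax = np.asarray(kmax, dtype=float)
    num = kmin + kmax
    den = kmin - kmax
    umb = np.abs(den) <= SI_UMBILIC_ATOL
    si = np.empty(np.broadcast(kmin, kmax).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = (2.0 / np.pi) * np.arctan(np.where(umb, 1.0, num) / np.where(umb, 1.0, den))
    si = np.where(umb, -np.sign(num / 2.0), si)
    return orientation * si


def curvedness(kmin, kmax):
    """CU = sqrt((kmax^2 + kmin^2) / 2)."""
    kmin = np.asarray(kmin, dtype=float)
    kmax = np.asarray(kmax, dtype=float)
    return np.sqrt((kmax * kmax + kmin * kmin) / 2.0)


def all_measures(
    field: PrincipalCurvatureField,
    si_orientation: int = 1,
) -> dict[Measure, ScalarField]:
    """All six measures of one curvature field as named scalar fields."""
    d = field.diameter_mm
    kmin, kmax = field.kmin, field.kmax
    return {
        Measure.KMIN: ScalarField(kmin.copy(), Measure.KMIN, d, field.mesh_id),
        Measure.KMAX: ScalarField(kmax.copy(), Measure.KMAX, d, field.mesh_id),
        Measure.MC: ScalarField(mean_curvature(kmin, kmax), Measure.MC, d, field.mesh_id),
        Measure.GC: ScalarField(gaussian_curvature(kmin, kmax), Measure.GC, d, field.mesh_id),
        Measure.SI: ScalarField(shape_index(kmin, kmax, si_orientation), Measure.SI, d, field.mesh_id),
        Measure.CU: ScalarField(curvedness(kmin, kmax), Measure.CU, d, field.mesh_id),
    }
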