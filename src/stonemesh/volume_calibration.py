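"""Layer-by-layer orthogonal volume estimation and shape-coefficient fit.

The mesh model's reliability rests on per-level x*y products tracking true
cross-sectional areas.  Summing x_i * y_i * dz over every slice gives a
bounding-box-like volume; regressing true volume on that sum yields a shape
coefficient k.  For elliptical cross-sections the true area is (pi/4)*x*y,
so k approaches pi/4 ~ 0.785 as spacing shrinks — the closed-form limit
against which the fit is checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .ct_measure import LevelMeasurement, VoxelMask, measure_all_slices

__all__ = ["CalibrationResult", "orthogonal_volume_sum", "orthogonal_sum_of_mask",
           "calibrate_k"]


@dataclass
class CalibrationResult:
    """OLS fit of true volume on the orthogonal layer sum.

    k is the slope (the shape coefficient), intercept in mm^3; an optional
    through-origin slope is reported alongside the default intercept fit.
    """

    k: float
    intercept: float
    r_squared: float
    n: int
    k_through_origin: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


def orthogonal_volume_sum(series: Sequence[LevelMeasurement], dz: float) -> float:
    """Sum x_i * y_i * dz over a full-resolution per-slice series, in mm^3.

    The series must be measured at every slice containing stone (native
    spacing), not at the sparser Q-sampling step.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    series = list(series)
    if not series:
        raise ValueError("orthogonal_volume_sum needs a non-empty series")
    return float(sum(m.x_mm * m.y_mm for m in series)) * dz


def orthogonal_sum_of_mask(stone: VoxelMask, *, rectangle_mode: bool = False) -> float:
    """Convenience: measure every slice of a mask and sum x*y*dz."""
    series = measure_all_slices(stone, rectangle_mode=rectangle_mode)
    return orthogonal_volume_sum(series, stone.spacing[0])


def calibrate_k(
    pairs: Sequence[tuple[float, float]], *, fit_intercept: bool = True
) -> CalibrationResult:
    """Fit true volume against the orthogonal layer sum by OLS.

    ``pairs`` holds (orthogonal_sum_mm3, true_volume_mm3).  The intercept
    fit is the default (matching conventional reporting); the slope of the
    physically cleaner through-origin fit is returned alongside.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise ValueError("need at least 3 (orthogonal_sum, true_volume) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate calibration input: zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    res0 = sm.OLS(y, x[:, None]).fit()
    if fit_intercept:
        k, intercept, r2 = res.params[1], res.params[0], res.rsquared
    else:
        k, intercept, r2 = res0.params[0], 0.0, res0.rsquared
    return CalibrationResult(
        k=float(k),
        intercept=float(intercept),
        r_squared=float(r2),
        n=len(pairs),
        k_through_origin=float(res0.params[0]),
    )
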