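"""Fluorescence-vs-immunoblot calibration of the reporter read-out.

Control-scaled Venus fluorescence is regressed (OLS, with intercept,
fluorescence as the response) on relative immunoblot band intensity over
transformants with a detectable fluorescence signal and a positive band.
Inverting the fitted line expresses a fluorescence value — in particular
the autofluorescence unit (fluorescence = 1) and the detection-interval
upper bound — as a relative protein level, i.e. the protein amount needed
before the plate reader can see the reporter above background.

Band intensities are used as supplied (relative to their population
average); no re-normalization is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detection import DetectionInterval
from .errors import AnalysisError


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of fluorescence (response) on relative band intensity."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_excluded: int
    protein_at_fluor_1: float
    protein_at_threshold: float


def fit_calibration(
    points: pd.DataFrame,
    interval: DetectionInterval,
    fluor_col: str = "control_scaled_venus",
    band_col: str = "relative_band_intensity",
) -> CalibrationFit:
    """Fit the fluorescence–protein calibration line.

    Points are filtered to those whose fluorescence lies outside the
    detection interval (detectable signal) and whose band intensity is
    positive; at least 3 must survive and the surviving band intensities
    must not be constant.
    """
    fluor = points[fluor_col].to_numpy(dtype=float)
    band = points[band_col].to_numpy(dtype=float)
    keep = (
        np.isfinite(fluor)
        & np.isfinite(band)
        & ((fluor < interval.lower) | (fluor > interval.upper))
        & (band > 0)
    )
    n_excluded = int((~keep).sum())
    x, y = band[keep], fluor[keep]
    if x.size < 3:
        raise AnalysisError(
            f"calibration fit needs >= 3 points after filtering, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in band intensities; fit undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    r_squared = float(model.rsquared)
    if slope > 0:
        protein_at_1 = (1.0 - intercept) / slope
        protein_at_threshold = (interval.upper - intercept) / slope
    else:
        protein_at_1 = math.nan
        protein_at_threshold = math.nan
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_points=int(x.size),
        n_excluded=n_excluded,
        protein_at_fluor_1=protein_at_1,
        protein_at_threshold=protein_at_threshold,
    )


def predict(fit: CalibrationFit, protein: float) -> float:
    """Predicted fluorescence at a relative protein level."""
    return fit.intercept + fit.slope * protein


def invert_at(fit: CalibrationFit, fluorescence: float) -> float:
    """Relative protein level corresponding to a fluorescence value.

    Requires a positive slope; returns ``(fluorescence - intercept) / slope``.
    """
    if fit.slope <= 0:
        raise AnalysisError("calibration slope is not positive; inversion undefined")
    return (float(fluorescence) - fit.intercept) / fit.slope
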