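"""Slice-index <-> apparent-mass calibration for gradient native gels.

A two-parameter log-linear model, log10(mass/kDa) = intercept + slope *
slice, fitted by least squares to marker species of known mass. This is
the standard calibration for gradient BN-PAGE: monotone by construction,
and the RMS residual diagnostics expose model inadequacy rather than
silently overfitting a spline through the markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_markers

logger = logging.getLogger(__name__)

__all__ = ["MassCalibration", "fit_mass_calibration", "apparent_mass", "slice_for_mass"]


@dataclass(frozen=True)
class MassCalibration:
    """Fitted log-linear mapping between slice index and apparent mass.

    ``slope`` must be negative: mass decreases down the gel. The mapping is
    defined over slices [1, n_slices]; evaluating outside that range is
    permitted but logged as extrapolation.
    """

    slope: float
    intercept: float
    n_markers: int
    rms_residual_log10: float
    n_slices: int

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError(
                f"calibration slope must be negative (got {self.slope:g}): "
                "apparent mass must decrease with slice index"
            )


def fit_mass_calibration(markers: pd.DataFrame, n_slices: int = 64) -> MassCalibration:
    """Least-squares fit of log10(mass) on peak slice.

    ``markers`` needs columns ``marker_name, mass_kda, peak_slice`` with at
    least two strictly co-monotone markers; with exactly two the fit
    interpolates them exactly.
    """
    validate_markers(markers)
    x = markers["peak_slice"].to_numpy(dtype=float)
    y = np.log10(markers["mass_kda"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > 0.1:
        logger.warning(
            "mass calibration RMS residual %.3f log10 units — the log-linear "
            "model may not describe this gel well", rms,
        )
    return MassCalibration(
        slope=float(slope),
        intercept=float(intercept),
        n_markers=len(markers),
        rms_residual_log10=rms,
        n_slices=n_slices,
    )


def apparent_mass(calibration: MassCalibration, slice_index: float) -> float:
    """Apparent molecular mass (kDa) at a (possibly fractional) slice."""
    if not (1.0 <= slice_index <= calibration.n_slices):
        logger.warning(
            "slice %.3g lies outside the calibrated range [1, %d]; extrapolating",
            slice_index, calibration.n_slices,
        )
    return float(10 ** (calibration.intercept + calibration.slope * slice_index))


def slice_for_mass(calibration: MassCalibration, mass_kda: float) -> float:
    """Inverse mapping: the slice where a given mass is expected to migrate."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    return float((np.log10(mass_kda) - calibration.intercept) / calibration.slope)
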