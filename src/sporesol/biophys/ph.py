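"""Ratiometric biosensor calibration and pH estimation.

The excitation ratio (405/488) of the sensor rises sigmoidally with pH.
Calibration fits a four-parameter logistic to background-subtracted
median ratios; sample pH is read off the analytic inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from ..errors import FitError, ParameterError, ValidationError


def four_param_logistic(ph, lower, upper, midpoint, slope):
    """ratio = lower + (upper - lower) / (1 + exp(-slope * (pH - midpoint)))"""
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (np.asarray(ph, float) - midpoint)))


@dataclass
class CalibrationCurve:
    """Fitted sigmoid mapping pH -> excitation ratio."""

    lower: float
    upper: float
    midpoint: float
    slope: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValidationError("upper asymptote must exceed lower")

    def ratio(self, ph):
        return four_param_logistic(ph, self.lower, self.upper, self.midpoint, self.slope)

    def inverse(self, ratio):
        """pH at a given ratio; only defined on the open (lower, upper)."""
        r = np.asarray(ratio, dtype=float)
        span = self.upper - self.lower
        return self.midpoint - np.log(span / (r - self.lower) - 1.0) / self.slope


def fit_ph_calibration(
    points,
    blank: float = 0.0,
) -> CalibrationCurve:
    """Fit the calibration sigmoid to (pH, median ratio) pairs.

    ``blank`` (autofluorescence ratio of unlabeled cells) is subtracted
    from every ratio before fitting.

    Raises
    ------
    FitError
        When fewer than 5 points are given, the data are flat (ratio
        range below 1e-6) or not monotone in pH, or the optimizer fails.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be (pH, ratio) pairs")
    if pts.shape[0] < 5:
        raise FitError("need at least 5 calibration points spanning the transition")
    order = np.argsort(pts[:, 0])
    ph = pts[order, 0]
    ratio = pts[order, 1] - blank

    if np.ptp(ratio) < 1e-6:
        raise FitError("flat calibration data: ratio does not vary with pH")
    rho = spearmanr(ph, ratio).statistic
    if not rho > 0.5:
        raise FitError(f"calibration ratios not monotone increasing in pH (rho={rho:.2f})")

    p0 = (float(ratio.min()), float(ratio.max()), float(np.median(ph)), 1.0)
    try:
        popt, _ = curve_fit(four_param_logistic, ph, ratio, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    lower, upper, midpoint, slope = (float(v) for v in popt)
    if slope < 0:  # equivalent parameterization; normalize to rising
        lower, upper, slope = upper, lower, -slope
    if not upper > lower:
        raise FitError("degenerate fit: asymptotes collapsed")
    residuals = ratio - four_param_logistic(ph, lower, upper, midpoint, slope)
    return CalibrationCurve(lower, upper, midpoint, slope, residuals)


def estimate_ph(
    curve: CalibrationCurve,
    sample_ratios,
    blank: float = 0.0,
) -> dict:
    """Invert the calibration for a sample of per-cell ratios.

    Ratios (after ``blank`` subtraction) outside the open asymptote
    interval are clamped just inside the curve limits and flagged.

    Returns a dict with ``median_ph``, ``ph`` (per cell) and
    ``clamped`` (boolean mask).
    """
    r = np.asarray(sample_ratios, dtype=float) - blank
    if r.size == 0:
        raise ParameterError("no sample ratios given")
    span = curve.upper - curve.lower
    eps = 1e-9 * span
    lo, hi = curve.lower + eps, curve.upper - eps
    clamped = (r <= curve.lower) | (r >= curve.upper)
    if clamped.all():
        raise ValidationError("all sample ratios fall outside the calibration range")
    if clamped.any():
        warnings.warn(f"{int(clamped.sum())} ratio(s) outside calibration range clamped",
                      stacklevel=2)
    ph = curve.inverse(np.clip(r, lo, hi))
    return {"median_ph": float(np.median(ph)), "ph": ph, "clamped": clamped}
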