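"""Growth-curve scoring, fluorescence heterogeneity and trehalose math."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..errors import ParameterError, ValidationError


def _as_curve(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, pd.DataFrame):
        t = curve.iloc[:, 0].to_numpy(dtype=float)
        od = curve.iloc[:, 1].to_numpy(dtype=float)
    else:
        t, od = (np.asarray(a, dtype=float) for a in curve)
    if t.size != od.size or t.size < 2:
        raise ParameterError("growth curve needs >= 2 (time, OD) points")
    if not (np.diff(t) > 0).all():
        raise ValidationError("times must be strictly increasing")
    if (od < 0).any():
        raise ValidationError("OD readings must be non-negative")
    return t, od


def growth_auc(curve, t_end: float) -> float:
    """Trapezoidal area of OD above its initial baseline on [t0, t_end]."""
    t, od = _as_curve(curve)
    if t_end < t[1]:
        raise ParameterError(f"t_end={t_end} precedes the second time point {t[1]}")
    t_end = min(t_end, t[-1])
    mask = t <= t_end
    tt, yy = t[mask], od[mask]
    if tt[-1] < t_end:  # interpolate the cut point
        y_end = float(np.interp(t_end, t, od))
        tt = np.append(tt, t_end)
        yy = np.append(yy, y_end)
    return float(np.trapezoid(yy - od[0], tt))


def detect_plateau_time(
    curve,
    tolerance: float = 0.02,
    n_consecutive: int = 3,
    smooth_window: int = 3,
) -> tuple[float, bool]:
    """First time the smoothed curve stays within ``tolerance`` of its
    maximum for ``n_consecutive`` readings.

    Returns (t_end, plateau_found); falls back to the last time point
    with a warning when no plateau is detected.
    """
    t, od = _as_curve(curve)
    kernel = np.ones(smooth_window) / smooth_window
    padded = np.concatenate([np.full(smooth_window // 2, od[0]), od,
                             np.full(smooth_window // 2, od[-1])])
    smooth = np.convolve(padded, kernel, mode="valid")[: od.size]
    top = smooth.max()
    near = smooth >= top * (1.0 - tolerance)
    run = 0
    for i, flag in enumerate(near):
        run = run + 1 if flag else 0
        if run >= n_consecutive:
            return float(t[i - n_consecutive + 1]), True
    warnings.warn("untreated curve never plateaus in window; using last time point",
                  stacklevel=2)
    return float(t[-1]), False


def heat_resistance_score(treated, untreated) -> float:
    """AUC of the treated curve over AUC of the untreated curve, both up
    to the time the untreated culture first reaches its plateau."""
    t_end, _ = detect_plateau_time(untreated)
    t_u, _ = _as_curve(untreated)
    t_end = max(t_end, t_u[1])  # AUC needs at least two points
    auc_untreated = growth_auc(untreated, t_end)
    if auc_untreated <= 0:
        raise ValidationError("untreated curve has no growth; score undefined")
    return growth_auc(treated, t_end) / auc_untreated


def heterogeneity_cv(pixels) -> float:
    """Sample standard deviation over mean of within-mask intensities."""
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size < 2:
        raise ParameterError("need at least 2 pixels")
    mean = x.mean()
    if mean <= 0:
        raise ValidationError("mean intensity must be positive")
    return float(x.std(ddof=1) / mean)


def trehalose_content(glucose_with_trehalase: float, glucose_without: float) -> float:
    """Trehalose in glucose equivalents: treated minus untreated reading,
    floored at zero (negative differences warn)."""
    a, b = float(glucose_with_trehalase), float(glucose_without)
    if a < 0 or b < 0:
        raise ValidationError("glucose readings must be non-negative")
    diff = a - b
    if diff < 0:
        warnings.warn(f"negative glucose difference ({diff:.4g}) floored to 0",
                      stacklevel=2)
        return 0.0
    return diff
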