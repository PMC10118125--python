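"""Single-particle detection, linking and mean squared displacement.

Coordinates enter in pixels, tracks and MSDs are in microns/seconds via
the microscope constants (defaults: 10/75 um per pixel, 2 frames/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from ..errors import ParameterError, ValidationError

DEFAULT_MPP = 10.0 / 75.0  # microns per pixel
DEFAULT_FPS = 2.0  # frames per second
DEFAULT_MASS_THRESHOLD = 200.0  # integrated intensity cutoff

TRACK_COLUMNS = ("particle", "frame", "x_um", "y_um", "t_s")


def detect_particles(
    image: np.ndarray,
    diameter: int,
    mass_threshold: float = DEFAULT_MASS_THRESHOLD,
) -> pd.DataFrame:
    """Locate bright spots in one image.

    Candidate local maxima are refined to intensity-weighted sub-pixel
    centroids inside a ``diameter`` window after subtracting the local
    background (median of the window border).  Candidates closer than
    ``diameter / 2`` are merged, keeping the one with the larger mass.

    Returns a DataFrame with columns ``x``, ``y`` (pixels, sub-pixel)
    and ``mass``; empty when nothing clears ``mass_threshold``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("image must be 2-D")
    if diameter % 2 == 0:
        raise ParameterError("diameter must be odd")
    if diameter > min(img.shape):
        raise ParameterError("diameter exceeds image size")
    if not np.isfinite(img).all() or (img < 0).any():
        raise ValidationError("image must be finite and non-negative")

    radius = diameter // 2
    smoothed = ndimage.gaussian_filter(img, sigma=max(diameter / 4.0, 1.0))
    maxima = (smoothed == ndimage.maximum_filter(smoothed, size=diameter)) & (
        smoothed > smoothed.mean()
    )
    candidates = np.argwhere(maxima)

    detections = []
    for row, col in candidates:
        r0, r1 = max(row - radius, 0), min(row + radius + 1, img.shape[0])
        c0, c1 = max(col - radius, 0), min(col + radius + 1, img.shape[1])
        window = img[r0:r1, c0:c1]
        border = np.concatenate(
            [window[0, :], window[-1, :], window[1:-1, 0], window[1:-1, -1]]
        )
        signal = np.clip(window - np.median(border), 0.0, None)
        mass = float(signal.sum())
        if mass < mass_threshold:
            continue
        rows_idx, cols_idx = np.mgrid[r0:r1, c0:c1]
        y = float((signal * rows_idx).sum() / mass)
        x = float((signal * cols_idx).sum() / mass)
        detections.append((x, y, mass))

    detections.sort(key=lambda d: -d[2])
    kept: list[tuple[float, float, float]] = []
    for x, y, mass in detections:  # merge near-duplicates, brightest wins
        if all((x - kx) ** 2 + (y - ky) ** 2 >= (diameter / 2.0) ** 2 for kx, ky, _ in kept):
            kept.append((x, y, mass))
    return pd.DataFrame(kept, columns=["x", "y", "mass"])


@dataclass
class _OpenTrack:
    particle: int
    last_frame: int
    x: float
    y: float


def link_tracks(
    detections: pd.DataFrame,
    max_disp: float,
    memory: int = 0,
    mpp: float = 1.0,
    fps: float = DEFAULT_FPS,
) -> pd.DataFrame:
    """Assemble per-frame detections into trajectories.

    Within each frame the assignment of detections to open tracks is the
    minimum total-squared-displacement matching (optimal per frame, via
    the Hungarian algorithm); a link longer than ``max_disp`` is never
    made.  A track missing from up to ``memory`` consecutive frames can
    be resumed; unmatched detections start new tracks.

    Parameters
    ----------
    detections
        DataFrame with ``frame``, ``x``, ``y`` (pixels).
    max_disp
        Maximal link length, in the *output* unit (after ``mpp``).
    mpp, fps
        Microns per pixel and frames per second for unit conversion.

    Returns
    -------
    DataFrame with columns ``particle``, ``frame``, ``x_um``, ``y_um``,
    ``t_s``, sorted by particle then frame.
    """
    if detections.empty:
        return pd.DataFrame(columns=list(TRACK_COLUMNS))
    req = {"frame", "x", "y"} - set(detections.columns)
    if req:
        raise ParameterError(f"detections missing column(s) {sorted(req)}")

    max_disp2 = float(max_disp) ** 2
    open_tracks: list[_OpenTrack] = []
    next_id = 0
    rows: list[tuple[int, int, float, float]] = []

    for frame, group in detections.sort_values("frame").groupby("frame", sort=True):
        frame = int(frame)
        pts = group[["x", "y"]].to_numpy(dtype=float) * mpp
        open_tracks = [t for t in open_tracks if frame - t.last_frame <= memory + 1]
        assigned_track: dict[int, int] = {}
        if open_tracks:
            prev = np.array([[t.x, t.y] for t in open_tracks])
            d2 = ((pts[:, None, :] - prev[None, :, :]) ** 2).sum(axis=2)
            big = max_disp2 * 1e6 + 1.0
            cost = np.where(d2 <= max_disp2, d2, big)
            # pad to square so every detection may stay unmatched
            n_det, n_trk = cost.shape
            size = n_det + n_trk
            padded = np.full((size, size), big)
            padded[:n_det, :n_trk] = cost
            padded[n_det:, n_trk:] = 0.0
            np.fill_diagonal(padded[:n_det, n_trk:], max_disp2 * 2.0)
            np.fill_diagonal(padded[n_det:, :n_trk], max_disp2 * 2.0)
            ri, ci = linear_sum_assignment(padded)
            for i, j in zip(ri, ci):
                if i < n_det and j < n_trk and d2[i, j] <= max_disp2:
                    assigned_track[i] = j
        for i, (x, y) in enumerate(pts):
            if i in assigned_track:
                trk = open_tracks[assigned_track[i]]
                trk.last_frame, trk.x, trk.y = frame, float(x), float(y)
                rows.append((trk.particle, frame, float(x), float(y)))
            else:
                trk = _OpenTrack(next_id, frame, float(x), float(y))
                next_id += 1
                open_tracks.append(trk)
                rows.append((trk.particle, frame, float(x), float(y)))

    out = pd.DataFrame(rows, columns=["particle", "frame", "x_um", "y_um"])
    out["t_s"] = out["frame"] / fps
    return out.sort_values(["particle", "frame"]).reset_index(drop=True)


def msd_curves(
    tracks: pd.DataFrame,
    max_lag: float | None = None,
    fps: float = DEFAULT_FPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-particle and ensemble mean squared displacement.

    MSD(tau) for one track is the average over *all* ordered position
    pairs separated by lag tau of their squared Euclidean displacement;
    the ensemble curve weights particles by their number of pairs.

    Parameters
    ----------
    tracks
        DataFrame with ``particle``, ``frame``, ``x_um``, ``y_um``.
    max_lag
        Largest lag in seconds (default: longest track span).

    Returns
    -------
    (imsd, emsd)
        ``imsd``: columns ``particle``, ``lag_s``, ``msd_um2``,
        ``n_pairs``; ``emsd``: ``lag_s``, ``msd_um2``, ``n_pairs``.
    """
    if tracks.empty:
        raise ParameterError("no tracks given")
    spans = tracks.groupby("particle")["frame"].agg(lambda f: f.max() - f.min())
    longest = float(spans.max()) / fps
    if max_lag is None:
        max_lag = longest
    elif max_lag > longest:
        warnings.warn(f"max_lag {max_lag} s exceeds longest track ({longest} s); truncated",
                      stacklevel=2)
        max_lag = longest
    max_lag_frames = int(round(max_lag * fps))

    records = []
    for particle, g in tracks.groupby("particle"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        pos = g[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(frames) < 2:
            continue
        index = {f: i for i, f in enumerate(frames)}
        for dlag in range(1, max_lag_frames + 1):
            sq = [
                ((pos[index[f + dlag]] - pos[i]) ** 2).sum()
                for i, f in enumerate(frames)
                if f + dlag in index
            ]
            if sq:
                records.append(
                    (particle, dlag / fps, float(np.mean(sq)), len(sq))
                )
    imsd = pd.DataFrame(records, columns=["particle", "lag_s", "msd_um2", "n_pairs"])
    if imsd.empty:
        raise ParameterError("tracks too short for any lag")

    grouped = imsd.groupby("lag_s")
    emsd = pd.DataFrame(
        {
            "lag_s": grouped.groups.keys(),
            "msd_um2": grouped.apply(
                lambda g: np.average(g["msd_um2"], weights=g["n_pairs"]),
                include_groups=False,
            ).to_numpy(),
            "n_pairs": grouped["n_pairs"].sum().to_numpy(),
        }
    ).reset_index(drop=True)
    return imsd, emsd


def estimate_diffusion(
    emsd: pd.DataFrame,
    fit_lags: tuple[float, float] = (0.5, 5.0),
) -> dict:
    """Diffusion coefficient from a 2-D ensemble MSD curve.

    Weighted least squares of MSD = 4 D tau through the origin over lags
    in ``fit_lags`` (inclusive), weights proportional to ``n_pairs``.

    Returns a dict with ``D`` (um^2/s), ``stderr``, ``n_lags``, and
    flags ``negative`` and ``nonlinear`` (large relative residual,
    e.g. ballistic input).
    """
    sel = emsd[(emsd["lag_s"] >= fit_lags[0]) & (emsd["lag_s"] <= fit_lags[1])]
    if sel.shape[0] < 2:
        raise ParameterError("need at least 2 lags inside fit range")
    tau = sel["lag_s"].to_numpy(dtype=float)
    msd = sel["msd_um2"].to_numpy(dtype=float)
    w = sel["n_pairs"].to_numpy(dtype=float) if "n_pairs" in sel else np.ones_like(tau)

    denom = float((w * tau * tau).sum())
    slope = float((w * tau * msd).sum()) / denom
    D = slope / 4.0
    resid = msd - slope * tau
    dof = max(len(tau) - 1, 1)
    var_slope = float((w * resid**2).sum()) / dof / denom
    stderr = np.sqrt(var_slope) / 4.0

    scale = float(np.abs(msd).max()) or 1.0
    rel_resid = float(np.sqrt(np.average(resid**2, weights=w))) / scale
    out = {
        "D": D,
        "stderr": stderr,
        "n_lags": int(len(tau)),
        "negative": D < 0,
        "nonlinear": rel_resid > 0.1,
    }
    if D < 0:
        warnings.warn("fitted diffusion coefficient is negative (noise-dominated)",
                      stacklevel=2)
    return out
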