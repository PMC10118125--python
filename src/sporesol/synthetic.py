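"""Synthetic input generators with planted ground truth.

Every generator is a pure function of its parameters and seed: the same
seed always reproduces byte-identical output.  Generated tables use the
same schemas the readers in :mod:`sporesol.quantio` expect, and every
dataset ships a truth table (``truth_``-prefixed columns) so downstream
recovery can be scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .solclust import (
    CLASS_LABELS,
    LABEL_GRADUAL_DESOL,
    LABEL_GRADUAL_SOL,
    LABEL_MOSTLY_PELLET,
    LABEL_MOSTLY_SUPERNATANT,
    LABEL_TRANSIENT,
)

DEFAULT_TIME_POINTS = ("0h", "1h", "3h", "6h", "veg")

#: design archetype trajectories over the default 5-point grid
ARCHETYPES: dict[str, tuple[float, ...]] = {
    LABEL_MOSTLY_PELLET: (0.85, 0.85, 0.85, 0.85, 0.85),
    LABEL_MOSTLY_SUPERNATANT: (0.15, 0.15, 0.15, 0.15, 0.15),
    LABEL_TRANSIENT: (0.80, 0.20, 0.70, 0.80, 0.80),
    LABEL_GRADUAL_DESOL: (0.20, 0.35, 0.50, 0.65, 0.80),
    LABEL_GRADUAL_SOL: (0.80, 0.65, 0.50, 0.35, 0.20),
}

#: class sizes of the default preset (sums to 895 retained proteins)
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    LABEL_MOSTLY_PELLET: 425,
    LABEL_MOSTLY_SUPERNATANT: 359,
    LABEL_TRANSIENT: 15,
    LABEL_GRADUAL_DESOL: 17,
    LABEL_GRADUAL_SOL: 79,
}


@dataclass
class SolubilitySimConfig:
    """Configuration of the solubility-dataset generator."""

    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    time_points: Sequence[str] = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    noise_sd: float = 0.05
    abundance_log_mean: float = 14.0
    abundance_log_sd: float = 1.5
    n_fail_coverage: int = 0
    n_fail_peptides: int = 0
    n_fail_detection: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ParameterError(f"unknown class label(s): {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ParameterError("class counts must be >= 0")
        if not 0.0 <= self.noise_sd <= 0.2:
            raise ParameterError("noise_sd must lie in [0, 0.2]")
        if len(self.time_points) != 5:
            raise ParameterError("archetypes are defined on a 5-point time grid")


def gen_solubility_dataset(
    config: SolubilitySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a fraction-quant table with planted trajectory classes.

    Per protein, replicate and time point, a true pellet share is drawn
    as archetype + Gaussian noise clipped to [0.01, 0.99]; pellet and
    supernatant abundances split a log-normal total accordingly.
    Coverage and peptide counts are drawn to pass the detection filters,
    except for the configured numbers of spiked failures (one mode each:
    low coverage, single peptide, one zero-total replicate cell).

    Returns
    -------
    (table, truth)
        ``table`` follows the fraction-quant schema; ``truth`` has one
        row per protein with ``truth_class`` and ``truth_filter_fate``
        (``pass`` / ``low_coverage`` / ``few_peptides`` /
        ``incomplete_series``).
    """
    n_planted = sum(config.class_counts.values())
    if n_planted == 0:
        raise ParameterError("zero proteins requested")
    rng = np.random.default_rng(config.seed)
    time_points = list(config.time_points)

    protein_rows = []
    for label in CLASS_LABELS:
        for _ in range(int(config.class_counts.get(label, 0))):
            protein_rows.append((label, "pass"))
    for _ in range(config.n_fail_coverage):
        protein_rows.append((LABEL_MOSTLY_PELLET, "low_coverage"))
    for _ in range(config.n_fail_peptides):
        protein_rows.append((LABEL_MOSTLY_PELLET, "few_peptides"))
    for _ in range(config.n_fail_detection):
        protein_rows.append((LABEL_MOSTLY_PELLET, "incomplete_series"))

    records = []
    truth = []
    for idx, (label, fate) in enumerate(protein_rows):
        pid = f"P{idx:05d}"
        archetype = np.array(ARCHETYPES[label])
        coverage = float(rng.uniform(0.15, 0.80))
        n_peptides = int(rng.integers(2, 40))
        if fate == "low_coverage":
            coverage = float(rng.uniform(0.01, 0.09))
        elif fate == "few_peptides":
            n_peptides = 1
        kill_cell = None
        if fate == "incomplete_series":
            kill_cell = (rng.integers(len(time_points)), rng.integers(1, config.n_replicates + 1))
        for t_idx, tp in enumerate(time_points):
            for rep in range(1, config.n_replicates + 1):
                p = float(np.clip(archetype[t_idx] + rng.normal(0.0, config.noise_sd), 0.01, 0.99))
                total = float(rng.lognormal(config.abundance_log_mean, config.abundance_log_sd))
                if kill_cell == (t_idx, rep):
                    total = 0.0
                for fraction, share in (("supernatant", 1.0 - p), ("pellet", p)):
                    records.append(
                        (pid, tp, rep, fraction, total * share, n_peptides, coverage)
                    )
        truth.append({"protein_id": pid, "truth_class": label, "truth_filter_fate": fate})

    table = pd.DataFrame(
        records,
        columns=["protein_id", "time_point", "replicate", "fraction",
                 "abundance", "n_peptides", "coverage"],
    )
    return table, pd.DataFrame(truth)


def gen_brownian_tracks(
    D: float,
    n_particles: int,
    n_frames: int,
    fps: float = 2.0,
    loc_noise: float = 0.0,
    seed: int = 0,
    box_um: float = 50.0,
) -> pd.DataFrame:
    """2-D Brownian trajectories with optional localization noise.

    Increments per axis are i.i.d. Gaussian with variance ``2 D dt``
    (so the true ensemble MSD is ``4 D tau``); localization noise adds
    i.i.d. Gaussian jitter of standard deviation ``loc_noise`` (um) to
    every reported position.
    """
    if D < 0:
        raise ParameterError("D must be >= 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    start = rng.uniform(0.0, box_um, size=(n_particles, 2))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_particles, n_frames - 1, 2))
    paths = np.concatenate([start[:, None, :], start[:, None, :] + steps.cumsum(axis=1)], axis=1)
    if loc_noise > 0:
        paths = paths + rng.normal(0.0, loc_noise, size=paths.shape)
    frames = np.tile(np.arange(n_frames), n_particles)
    particles = np.repeat(np.arange(n_particles), n_frames)
    return pd.DataFrame(
        {
            "particle": particles,
            "frame": frames,
            "x_um": paths[:, :, 0].ravel(),
            "y_um": paths[:, :, 1].ravel(),
            "t_s": frames / fps,
        }
    )


def render_spots(
    positions,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 50.0,
    sigma: float = 1.5,
    background: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render point sources as Gaussian spots on a noisy background.

    ``positions`` is a sequence of (x, y) pixel coordinates (x = column,
    y = row, matching detector output).
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, float(background))
    for x, y in positions:
        img += amplitude * np.exp(-((cols - x) ** 2 + (rows - y) ** 2) / (2.0 * sigma**2))
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, size=shape), 0.0, None)
    return img


def gen_ph_calibration_data(
    params: tuple[float, float, float, float] = (0.2, 1.4, 7.0, 1.1),
    ph_grid: Sequence[float] = tuple(np.arange(5.0, 9.01, 0.5)),
    noise_cv: float = 0.0,
    n_cells: int = 2000,
    sample_true_phs: Sequence[float] = (),
    sample_noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Calibration medians from a known sigmoid, plus per-cell ratios.

    Returns
    -------
    (calibration, samples)
        ``calibration``: array of (pH, median ratio) rows with
        multiplicative noise of coefficient of variation ``noise_cv``.
        ``samples``: true pH -> per-cell ratio array (``n_cells`` cells,
        multiplicative noise ``sample_noise_cv``).
    """
    lower, upper, midpoint, slope = params
    if not upper > lower:
        raise ParameterError("upper asymptote must exceed lower")
    rng = np.random.default_rng(seed)
    from .biophys.ph import four_param_logistic

    grid = np.asarray(list(ph_grid), dtype=float)
    clean = four_param_logistic(grid, lower, upper, midpoint, slope)
    noisy = clean * (1.0 + rng.normal(0.0, noise_cv, size=grid.size)) if noise_cv > 0 else clean
    calibration = np.column_stack([grid, noisy])

    samples: dict[float, np.ndarray] = {}
    for true_ph in sample_true_phs:
        r = four_param_logistic(true_ph, lower, upper, midpoint, slope)
        cells = r * (1.0 + rng.normal(0.0, sample_noise_cv, size=n_cells))
        samples[float(true_ph)] = cells
    return calibration, samples


def logistic_od(t, K: float, r: float, midpoint: float, baseline: float = 0.01):
    """Logistic growth curve used by the growth generator."""
    return baseline + K / (1.0 + np.exp(-r * (np.asarray(t, float) - midpoint)))


def gen_growth_curves(
    K: float = 1.0,
    r: float = 1.0,
    midpoint: float = 5.0,
    lag: float = 0.0,
    kill_fraction: float = 0.0,
    noise_sd: float = 0.0,
    times: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired treated/untreated growth curves.

    Untreated OD follows a logistic; the treated curve is delayed by
    ``lag`` hours and its carrying capacity scaled by the surviving
    fraction ``1 - kill_fraction``.

    Returns (treated, untreated) DataFrames with columns ``time_h``,
    ``od``.
    """
    if K <= 0 or r <= 0:
        raise ParameterError("K and r must be positive")
    if not 0.0 <= kill_fraction <= 1.0:
        raise ParameterError("kill_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.asarray(times if times is not None else np.arange(0.0, 24.01, 0.25), dtype=float)
    untreated = logistic_od(t, K, r, midpoint)
    treated = logistic_od(t, K * (1.0 - kill_fraction), r, midpoint + lag)
    if noise_sd > 0:
        untreated = np.clip(untreated + rng.normal(0.0, noise_sd, t.size), 0.0, None)
        treated = np.clip(treated + rng.normal(0.0, noise_sd, t.size), 0.0, None)
    return (
        pd.DataFrame({"time_h": t, "od": treated}),
        pd.DataFrame({"time_h": t, "od": untreated}),
    )


def gen_cell_image(
    shape: tuple[int, int] = (64, 64),
    n_foci: int = 0,
    focus_amplitude: float = 0.0,
    diffuse_amplitude: float = 10.0,
    background: float = 0.0,
    focus_sigma: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disk-masked cell with diffuse signal plus bright foci.

    Returns (image, mask); total integrated in-mask signal is
    ``diffuse_amplitude * mask_area + n_foci * focus_amplitude *
    2 * pi * focus_sigma**2`` (before noise), so foci/diffuse pairs can
    be intensity-matched by trading amplitude for focus count.
    """
    if focus_amplitude < 0 or diffuse_amplitude < 0 or background < 0:
        raise ParameterError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius = min(shape) * 0.4
    mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
    img = np.full(shape, float(background))
    img[mask] += diffuse_amplitude
    for _ in range(n_foci):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, radius * 0.7)
        fy, fx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        img += focus_amplitude * np.exp(
            -((cols - fx) ** 2 + (rows - fy) ** 2) / (2.0 * focus_sigma**2)
        )
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, size=shape), 0.0, None)
    return img, mask
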