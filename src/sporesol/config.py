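"""Pipeline configuration: defaults, YAML loading, dotted overrides.

Unknown keys are rejected so typos never silently fall back to
defaults.  A resolved copy of the configuration is written next to the
outputs of every run.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .synthetic import DEFAULT_CLASS_COUNTS, DEFAULT_TIME_POINTS

#: sections whose keys are user data, not schema (never rejected)
_OPEN_SECTIONS = {
    ("simulate", "class_counts"),
    ("simulate", "tracks", "conditions"),
    ("columns",),
}

DEFAULT_CONFIG: dict[str, Any] = {
    "out_dir": "results",
    "seed": 1,
    "time_points": list(DEFAULT_TIME_POINTS),
    "columns": {},
    "input": {
        "fraction_quant": None,
        "trajectory_matrix": None,
        "annotations": None,
        "edges": None,
        "tracks": None,
        "ph_calibration": None,
        "ph_samples": None,
        "growth": None,
    },
    "filters": {"min_coverage": 0.10, "min_peptides": 2},
    "clustering": {"n_clusters": 5, "linkage": "complete", "metric": "euclidean"},
    "labeling": {"static_range": 0.25, "dip_margin": 0.20, "trend_margin": 0.15},
    "enrichment": {"min_term_size": 2},
    "tracking": {
        "mpp": 10.0 / 75.0,
        "fps": 2.0,
        "mass_threshold": 200.0,
        "max_disp": 1.0,
        "memory": 0,
        "fit_lags": [0.5, 5.0],
        "msd_lag_s": 1.0,
    },
    "ph": {"blank": 0.0},
    "simulate": {
        "class_counts": dict(DEFAULT_CLASS_COUNTS),
        "n_replicates": 3,
        "noise_sd": 0.05,
        "n_fail_coverage": 5,
        "n_fail_peptides": 5,
        "n_fail_detection": 5,
        "tracks": {
            "conditions": {"vegetative": 5.0e-2, "spore": 5.0e-4},
            "n_particles": 30,
            "n_frames": 120,
            "loc_noise": 0.02,
        },
        "ph": {
            "params": [0.2, 1.4, 7.0, 1.1],
            "grid_start": 5.0,
            "grid_stop": 9.0,
            "grid_step": 0.5,
            "calibration_noise_cv": 0.02,
            "n_cells": 2000,
            "sample_true_phs": [5.9, 6.2, 7.3, 7.4],
            "sample_noise_cv": 0.05,
        },
        "growth": {
            "K": 1.0,
            "r": 1.0,
            "midpoint": 5.0,
            "lag": 2.0,
            "kill_fraction": 0.3,
            "noise_sd": 0.0,
        },
    },
}


def _merge(base: dict, user: dict, path: tuple[str, ...] = ()) -> dict:
    out = copy.deepcopy(base)
    for key, value in user.items():
        if path in _OPEN_SECTIONS:
            out[key] = copy.deepcopy(value)
            continue
        if key not in base:
            dotted = ".".join(path + (str(key),))
            raise ConfigError(f"unknown configuration key: {dotted!r}")
        if path + (key,) in _OPEN_SECTIONS:
            out[key] = copy.deepcopy(value)  # user data replaces, never merges
        elif isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, path + (key,))
        else:
            out[key] = copy.deepcopy(value)
    return out


def _parse_scalar(text: str) -> Any:
    return yaml.safe_load(text)


def apply_override(config: dict, dotted: str, value: str) -> None:
    """Apply one ``a.b.c=value`` override in place."""
    keys = dotted.split(".")
    node = config
    trail: tuple[str, ...] = ()
    for key in keys[:-1]:
        if key not in node or not isinstance(node[key], dict):
            raise ConfigError(f"unknown configuration key: {dotted!r}")
        trail = trail + (key,)
        node = node[key]
    leaf = keys[-1]
    if leaf not in node and trail not in _OPEN_SECTIONS:
        raise ConfigError(f"unknown configuration key: {dotted!r}")
    node[leaf] = _parse_scalar(value)


def load_config(path: str | Path | None = None, overrides: list[str] | None = None) -> dict:
    """Merge defaults with a YAML file and ``key=value`` overrides."""
    user: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
        user = raw
    config = _merge(DEFAULT_CONFIG, user)
    for item in overrides or []:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        dotted, value = item.split("=", 1)
        apply_override(config, dotted, value)
    return config


def dump_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
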