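"""Run configuration: defaults, YAML loading, and validation.

Every tunable of the extraction and evaluation stages lives here so a run can
be reproduced from its serialized config alone. Unknown keys are rejected.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "pause": {
        "min_pause_s": 0.150,
        "min_speech_s": 0.035,
        "amp_thresh": 0.04,
        "env_window_s": 0.010,
        "sd_ddof": 0,
    },
    "rhythm": {
        "n_channels": 28,
        "fmin": 100.0,
        "fmax": 10000.0,
        "env_rate": 100.0,
        "nfft": 2048,
        "ar_norm": None,  # None: mean articulation rate of the HC rows
    },
    "visibility": {"L_ms": 10.0},
    "f0": {
        "window_ms": {"male": 20.0, "female": 10.0},
        "range_hz": {"male": [60.0, 300.0], "female": [100.0, 500.0]},
        "voicing_threshold": 0.6,
        "hop_s": 0.010,
    },
    "wpd": {"wavelet": "db4", "level": 3},
    "mfcc": {
        "n_mfcc": 13,
        "frame_s": 0.025,
        "hop_s": 0.010,
        "n_filters": 26,
        "preemphasis": 0.97,
    },
    "rqa": {"m": 3, "tau": 5, "eps": 0.2, "lmin": 2, "segment_s": 1.0},
    "cpp": {"frame_ms": 40.0, "hop_ms": 20.0, "qmin_hz": 60.0, "qmax_hz": 330.0},
    "factor": {
        "k": None,  # None: choose by parallel analysis
        "pa_resamples": 100,
        "pa_percentile": 95.0,
        "oblimin_gamma": 0.0,
    },
    "regression": {"level": "sample"},
    "classify": {
        "algos": ["svm_rbf", "rf"],
        "folds": 5,
        "repeats": 10,
        "rf_trees": 500,
        "group_by_subject": False,
    },
    "cluster": {"k_min": 1, "k_max": 6, "gap_B": 100},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and not _is_leaf_dict(here):
            if not isinstance(value, dict):
                raise TypeError(f"config key {here} expects a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _is_leaf_dict(path: str) -> bool:
    # dict-valued leaves whose keys are data, not config structure
    return path in {"f0.window_ms", "f0.range_hz"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and a dict of overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
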