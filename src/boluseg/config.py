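"""YAML run configuration: defaults, merging, and run-directory serialization."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_run_config", "save_run_config"]

DEFAULTS: dict = {
    "seed": 0,
    "phantom": {
        "height": 64,
        "width": 64,
        "n_blobs": 5,
        "blob_amplitude": 0.4,
        "base_intensity": 0.35,
        "noise_sigma": 0.005,
        "jitter_px": 1,
        "amp_jitter": 0.5,
        "periodic": True,
        "anomaly": {
            "semi_axes": [7, 5],
            "mode": "transplanted",
            "delta": 0.3,
            "count_per_frame": 1,
            "min_source_contrast": 0.15,
            "feather_px": 1.5,
        },
        "n_train": 200,
        "n_test_clean": 10,
        "n_test_anom": 30,
    },
    "preprocess": {
        "target_size": 256,
        "border_threshold": 0.02,
        "use_pe": True,
        "roi_margins": [0.10, 0.10, 0.10],
    },
    "model": {
        "encoder_widths": [64, 128, 256],
        "dropout_rate": 0.1,
        "padding": "zeros",
    },
    "loss": {"lambda_edge": 0.05},
    "train": {
        "learning_rate": 0.01,
        "batch_size": 16,
        "epochs": 100,
        "noise_aug_sigma": 0.02,
        "validation_fraction": 0.1,
    },
    "segment": {
        "multiplier": 1.0,
        "calibration_fraction": 0.1,
        "min_component_area": 0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_run_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with an optional YAML file, overlaid with overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def save_run_config(cfg: dict, out_dir: str | Path) -> Path:
    """Write the fully resolved config into the run directory for replay."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
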