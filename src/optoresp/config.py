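"""Run configuration with the analysis defaults, loaded from YAML.

One flat mapping with per-module sections; every numeric default is the
value the corresponding analysis function documents. Unknown keys are
rejected before any stage runs so typos cannot silently fall back to
defaults.
"""
from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

from .types import ConfigurationError

DEFAULTS = {
    "ephys": {
        "filter_window": 0.25,        # s, sliding-median spike removal
        "baseline_start": 0.1,        # s after trace onset
        "baseline_len": 0.9,          # s baseline-percentile window
        "percentiles": [10.0, 90.0],  # baseline variability thresholds
        "eval_window": 1.0,           # s post-onset classification window
        "min_duration": 0.05,         # s consecutive-crossing requirement
        "auc_horizon": 1.0,           # s, ±window for trapezoid AUC
        "bin_width": 0.25,            # s firing-rate bins
        "sg_windows": [0.4, 0.2, 0.1, 0.05],  # s Savitzky-Golay windows
        "sg_order": 4,
        "min_cluster_n": 5,           # Wilcoxon per-cluster minimum
        "pooled_percentiles": True,
    },
    "calcium": {
        "gaussian_width_px": 2.0,
        "gaussian_interpret": "sigma",
        "reference_frames": 50,
        "f0_fraction": 0.10,
        "f0_ranking": "per_pixel",
        "baseline_window": 5.0,       # s before first stimulus
        "percentiles": [20.0, 80.0],
        "post_margin": 5.0,           # s after stimulus offset
        "run_fraction": 0.25,
        "pre_window": 5.0,            # s pre-onset AUC window
        "center_window": 1.0,         # s baseline-median window for ΔAUC
        "heatmap_pre_window": 1.0,
    },
    "connectome": {
        "min_syn": 5,
        "score_threshold": 0.62,
    },
    "expression": {
        "markers": ["Ilp2", "Ilp3", "Ilp5"],
        "cutoffs": [5.0, 10.0],
    },
    "simulate": {
        "seed": 0,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and/or a mapping of overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        import yaml
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("configuration file must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash for provenance blocks."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
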