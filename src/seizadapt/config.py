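"""Layered YAML configuration and run provenance.

Precedence is defaults < config file < command-line overrides. Every CLI
run writes a :class:`RunManifest` next to its outputs so any artifact can
be traced back to the exact configuration, seeds and code version that
produced it.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__

DEFAULTS: dict = {
    "cohort": {
        "n_subjects": 6,
        "n_channels": 23,
        "sampling_rate_hz": 256,
        "record_duration_s": 7200.0,
        "seizures_per_subject": 1,
        "shift_strength": 0.5,
        "master_seed": 0,
        "preictal_horizon_s": 3600.0,
        "preictal_gain": 2.0,
    },
    "preprocess": {
        "notch_hz": 50.0,
        "band_hz": [0.5, 70.0],
        "preictal_horizon_s": 3600.0,
        "postictal_exclusion_s": 3600.0,
        "window_s": 10.0,
        "min_channels": 23,
        "balance_seed": 0,
        "resample_hz": None,
    },
    "model": {"F1": 8, "F2": 2, "F3": 16, "dropout_p": 0.25},
    "train": {
        "lr": 0.005,
        "beta1": 0.9,
        "beta2": 0.999,
        "max_epochs": 500,
        "patience_epochs": 20,
        "batch_size": 64,
        "seed": 0,
        "adapt_method": "none",
        "lambda_mode": "schedule",
        "lambda_value": 1.0,
    },
    "evaluate": {
        "fractions": [0.6, 0.2, 0.2],
        "source_val_fraction": 0.2,
        "transductive": True,
    },
}


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in extra.items():
        if (key in out and isinstance(out[key], dict)
                and isinstance(value, dict)):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


@dataclass
class RunManifest:
    verb: str
    config: dict
    seeds: dict = field(default_factory=dict)
    preprocess_hash: str | None = None
    outputs: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    version: str = __version__
    created: str = ""

    def write(self, out_dir) -> Path:
        self.created = self.created or time.strftime("%Y-%m-%dT%H:%M:%S")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path
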