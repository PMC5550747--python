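"""Run configuration: YAML/JSON loading, validation, and defaults.

Defaults follow the headline parameterizations of the model: growth rate
0.06/h-scale units, growth duration 40, transmission weights (0.1, 0.6),
inocula of 5e6 cells for within-patch runs and 5000 founders for
passaging.  Unknown keys warn (forward compatibility) rather than error;
invariant violations are aggregated into a single report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULTS", "load_config", "validate_config", "config_hash"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out": "results",
    "log_level": "info",
    "within_patch": {
        "r": 0.06,
        "c": 0.03,
        "t_end": 40.0,
        "P0": 5e6,
        "B0": 0.0,
        "d": 0.0,
        "g": 0.0,
        "growth_form": "none",
        "n_times": 201,
    },
    "landscape": {
        "r_values": [0.02, 0.04, 0.06, 0.08, 0.1, 0.12],
        "t_values": [40.0],
        "k_resolution": 101,
    },
    "environment": {
        "level": "high",
        "convention": "cv",
        "mu_r": 0.06,
        "mu_t": 40.0,
        "mu_kp": 0.1,
        "mu_kb": 0.6,
    },
    "passaging": {
        "c_grid": [round(0.01 * i, 4) for i in range(1, 21)],
        "treatments": ["low", "mid", "high"],
        "n_passages": 10,
        "n_replicates": 100,
        "founders0": 5000.0,
        "c_mode": "absolute",
    },
    "geometry": {
        "dimensionality": 2,
        "geometry": "substratum",
        "active_depth": 3,
        "domain_extent": [60, None],
        "division_time": 1.0,
        "inoculum": 4,
        "t_end": 80.0,
    },
}

_VALIDATORS = {
    ("within_patch", "r"): lambda v: v >= 0,
    ("within_patch", "c"): lambda v: v >= 0,
    ("within_patch", "t_end"): lambda v: v >= 0,
    ("within_patch", "P0"): lambda v: v > 0,
    ("within_patch", "B0"): lambda v: v >= 0,
    ("within_patch", "d"): lambda v: v >= 0,
    ("within_patch", "g"): lambda v: v >= 0,
    ("within_patch", "growth_form"): lambda v: v in ("none", "linear", "quadratic"),
    ("landscape", "k_resolution"): lambda v: v >= 2,
    ("environment", "level"): lambda v: v in ("low", "mid", "high", "fixed"),
    ("environment", "convention"): lambda v: v in ("cv", "literal", "mean_squared_over_divisor", "mean_over_divisor"),
    ("passaging", "n_passages"): lambda v: v > 0,
    ("passaging", "n_replicates"): lambda v: v > 0,
    ("passaging", "founders0"): lambda v: v > 0,
    ("passaging", "c_mode"): lambda v: v in ("absolute", "relative"),
    ("geometry", "dimensionality"): lambda v: v in (1, 2, 3),
    ("geometry", "geometry"): lambda v: v in ("radial", "substratum"),
    ("geometry", "active_depth"): lambda v: v >= 1,
    ("geometry", "inoculum"): lambda v: v >= 1,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML (or JSON — YAML is a superset) config file; None gives
    an empty config, i.e. full defaults."""
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return data


def validate_config(config: dict[str, Any] | str | Path | None) -> dict[str, Any]:
    """Normalize a (possibly partial) config against the defaults.

    Missing keys are filled from DEFAULTS; unknown keys emit a warning and
    are carried through; invariant violations are collected and raised
    together with their field paths.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    merged = json.loads(json.dumps(DEFAULTS))  # deep copy
    errors: list[str] = []
    for section, value in config.items():
        if section not in DEFAULTS:
            warnings.warn(f"unknown config section {section!r} (ignored by core, carried through)")
            merged[section] = value
            continue
        if isinstance(DEFAULTS[section], dict):
            if not isinstance(value, dict):
                errors.append(f"{section}: expected a mapping")
                continue
            for key, v in value.items():
                if key not in DEFAULTS[section]:
                    warnings.warn(f"unknown config key {section}.{key!r} (carried through)")
                merged[section][key] = v
        else:
            merged[section] = value
    for (section, key), check in _VALIDATORS.items():
        v = merged.get(section, {}).get(key)
        if v is not None:
            try:
                ok = check(v)
            except TypeError:
                ok = False
            if not ok:
                errors.append(f"{section}.{key}: invalid value {v!r}")
    for c in merged["passaging"]["c_grid"]:
        if c < 0:
            errors.append(f"passaging.c_grid: negative colonization rate {c!r}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return merged


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a normalized config, for output metadata."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
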