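"""YAML run configuration: allometric coefficients, filters and scenario knobs.

A config file may override any subset of::

    coefficients: {a0, a1, a2, a3}
    carbon_fraction: 0.5
    dbh_min_cm: 10.0
    include_palms: false
    large_seeded: {percentile: 75}        # or {fixed_cutoff_cm: 1.8}
    ba_tolerance: 0.01
    large_tree_threshold_cm: 70.0
    column_map: {site: ..., plot: ..., taxon: ..., dbh: ...}
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .carbon import AllometricCoefficients
from .traits import LargeSeededRule

__all__ = ["DEFAULTS", "load_config", "coefficients_from_config", "rule_from_config"]

DEFAULTS: dict[str, Any] = {
    "coefficients": {},
    "carbon_fraction": 0.5,
    "dbh_min_cm": 10.0,
    "include_palms": False,
    "large_seeded": {"percentile": 75.0},
    "ba_tolerance": 0.01,
    "large_tree_threshold_cm": 70.0,
    "column_map": {},
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a YAML config file (may be None) over the defaults."""
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is None:
        return config
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    for key, value in user.items():
        if key not in config:
            raise KeyError(f"unknown config key {key!r}; known: {sorted(config)}")
        if isinstance(config[key], dict):
            config[key].update(value or {})
        else:
            config[key] = value
    return config


def coefficients_from_config(config: dict[str, Any]) -> AllometricCoefficients:
    return AllometricCoefficients(
        **config["coefficients"], carbon_fraction=config["carbon_fraction"]
    )


def rule_from_config(config: dict[str, Any]) -> LargeSeededRule:
    spec = config["large_seeded"]
    if "fixed_cutoff_cm" in spec:
        return LargeSeededRule(fixed_cutoff_cm=spec["fixed_cutoff_cm"])
    return LargeSeededRule(percentile=spec.get("percentile", 75.0))
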