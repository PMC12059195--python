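"""Configuration loading.

All calibration constants for the synthetic cohort and the analysis stages
live in one documented YAML file (``heatwear/data/defaults.yaml``). User
configuration files are deep-merged over those defaults, so a config file
only needs to state what it overrides.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict[str, Any]:
    """Return the packaged default configuration as a nested dict."""
    text = resources.files("heatwear.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load configuration, merging an optional user YAML over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path!s} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    _validate(cfg)
    return cfg


def _validate(cfg: Mapping[str, Any]) -> None:
    env = cfg["environment"]
    for loc in ("outdoor", "indoor"):
        if not 0 <= env[loc]["peak_hour"] < 24:
            raise ValueError(f"{loc} peak_hour must lie in [0, 24)")
        if env[loc]["noise_sd"] < 0:
            raise ValueError(f"{loc} noise_sd must be >= 0")
    for device, params in cfg["missingness"].items():
        for key in ("failure_prob", "gap_prob"):
            if not 0 <= params[key] <= 1:
                raise ValueError(f"missingness.{device}.{key} must be a probability")
    if cfg["strain"]["component_weight"] <= 0:
        raise ValueError("strain.component_weight must be positive")
    lo, hi = cfg["cohort"]["age_range"]
    if not (0 < lo < hi):
        raise ValueError("cohort.age_range must be increasing and positive")
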