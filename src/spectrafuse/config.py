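"""Run configuration: nested defaults, strict merging, YAML loading.

Unknown keys are rejected so that typos cannot silently disable a stage.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["DEFAULT_CONFIG", "merge_config", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "coregister": {
        "max_distance": None,        # um; None = assign every source pixel
    },
    "snip": {
        "raman_window": 40,          # channels
        "raman_lls": False,
        "maldi_window": 25,          # channels of the profile m/z axis
        "maldi_lls": True,
        "order": "increasing",
    },
    "raman": {
        "target_axis": None,         # [start, stop, step] cm^-1, or None
        "spike_z": 8.0,
        "norm": "l2",                # l2 | l1 | total_intensity
    },
    "maldi": {
        "tolerance_ppm": 200.0,
        "snr": 10.0,
        "max_shift": 0.5,            # Da
        "anchor_quantile": 0.99,
        "phase_model": "offset",     # offset | linear
        "norm": "tic",
    },
    "fuse": {
        "weight": "auto",            # "auto" = l1-norm ratio, or a number
    },
    "evaluate": {
        "components": 10,
        "sweep": None,               # e.g. [1, 20] inclusive integer range
        "pcs": [1, 2, 3],            # 1-based for reports
    },
}


def merge_config(overrides: dict | None, base: dict | None = None) -> dict:
    """Deep-merge ``overrides`` into the defaults, rejecting unknown keys."""
    merged = copy.deepcopy(base if base is not None else DEFAULT_CONFIG)
    if not overrides:
        return merged
    _merge_into(merged, overrides, path="")
    return merged


def _merge_into(dst: dict, src: dict, path: str) -> None:
    for key, value in src.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in dst:
            raise ParameterError(f"unknown config key: {here}")
        if isinstance(dst[key], dict) and not isinstance(value, dict):
            raise ParameterError(f"config key {here} must be a mapping")
        if isinstance(dst[key], dict):
            _merge_into(dst[key], value, here)
        else:
            dst[key] = value


def load_config(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    return merge_config(data)
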