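"""Load approach and model configurations from YAML or JSON files."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .npsi import NPsiParams
from .pooling import PoolParams
from .stimulus import ApproachSpec

__all__ = ["load_config", "approach_spec_from_dict", "npsi_params_from_dict"]

_SPEC_KEYS = {"l": "half_size_l", "v": "velocity_v", "x0": "initial_distance_x0"}


def approach_spec_from_dict(d: dict) -> ApproachSpec:
    """Build an ApproachSpec from a config mapping.

    Accepts both the short keys ``l``, ``v``, ``x0`` and the full field
    names; extra keys not belonging to the spec are ignored.
    """
    kwargs = {}
    for key, value in d.items():
        name = _SPEC_KEYS.get(key, key)
        if name in ApproachSpec.__dataclass_fields__ and value is not None:
            kwargs[name] = value
    return ApproachSpec(**kwargs)


def npsi_params_from_dict(d: dict) -> NPsiParams:
    """Build NPsiParams (including the inhibitory pool) from a mapping."""
    pool_keys = {"N": "n_channels_N", "sigma": "noise_sigma",
                 "delta0": "threshold_delta0", "gamma": "gain_gamma"}
    pool_kwargs = {}
    kwargs = {}
    for key, value in d.items():
        if value is None:
            continue
        if key in pool_keys:
            pool_kwargs[pool_keys[key]] = value
        elif key in PoolParams.__dataclass_fields__:
            pool_kwargs[key] = value
        elif key in NPsiParams.__dataclass_fields__ and key != "pool":
            kwargs[key] = value
    if pool_kwargs:
        kwargs["pool"] = PoolParams(**{**PoolParams().__dict__, **pool_kwargs})
    return NPsiParams(**kwargs)


def load_config(path) -> dict:
    """Read a YAML (or JSON) configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
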