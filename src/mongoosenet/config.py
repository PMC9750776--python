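"""Run configuration: defaults, validation, and per-stage seed derivation.

A run is driven by one YAML file (flat keys plus nested blocks).  Unknown
keys are rejected before any computation.  All randomness flows from one
master seed; each stage derives its own stream by hashing the stage name
into the seed, so re-running a single stage reproduces the corresponding
part of a full pipeline run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "config_hash", "derive_seed"]

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "outdir": "runs/latest",
    "data": {
        "path": None,               # CSV path; when None a synthetic preset is used
        "preset": "cleveland-like",
        "synth": {},                # SynthConfig overrides for the preset
        "sentinel": "?",
        "label_column": None,
        "binarize": "zero-vs-rest",
    },
    "features": {
        "o": None,                  # default ceil(0.6*n)
        "z": None,                  # default ceil(0.5*o)
        "rank_by_abs": True,
        "congruence_form": "tucker",
    },
    "network": {
        "spec": "micro",            # micro | full8
        "weight_bound": 1.0,
    },
    "dmoa": {
        "n_mongooses": 30,
        "max_iter": 150,
        "peep": 2.0,
        "n_babysitters": 3,
        "exchange_period": None,
        "patience": 50,
        "alpha_weighting": "printed",
    },
    "protocol": {
        "split": [0.9],
        "kfold": [],
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                raise ValueError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(config: dict) -> dict:
    """Merge onto defaults, rejecting unknown keys and bad combinations."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    o, z = cfg["features"]["o"], cfg["features"]["z"]
    if o is not None and o < 2:
        raise ValueError("features.o must be >= 2")
    if z is not None and z < 1:
        raise ValueError("features.z must be >= 1")
    if o is not None and z is not None and z >= o:
        raise ValueError(f"features must satisfy o > z, got o={o}, z={z}")
    if cfg["dmoa"]["n_mongooses"] < 2:
        raise ValueError("dmoa.n_mongooses must be >= 2")
    if cfg["dmoa"]["max_iter"] < 0:
        raise ValueError("dmoa.max_iter must be >= 0")
    for frac in cfg["protocol"]["split"]:
        if not 0 < frac < 1:
            raise ValueError(f"protocol.split fraction {frac} must lie in (0, 1)")
    for k in cfg["protocol"]["kfold"]:
        if k < 2:
            raise ValueError(f"protocol.kfold value {k} must be >= 2")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    return cfg


def load_config(path=None) -> dict:
    """Read a YAML config file (or use pure defaults) and validate it."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def config_hash(config: dict) -> str:
    """Short content hash recorded in every output artifact."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def derive_seed(master: int, stage: str) -> int:
    """Stage-specific seed below 2^31, stable across runs."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31)
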