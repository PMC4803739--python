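"""YAML configuration for experiment runs.

A config is a nested mapping with blocks ``stimuli``, ``frontend``,
``network`` and ``experiment``; anything omitted falls back to the
simulation defaults (Table-level constants of the model).  Runs emit a
resolved copy of the configuration they actually used.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .network import NetworkParams

__all__ = ["default_config", "load_config", "resolve_network_params", "dump_config"]


def default_config() -> dict:
    return {
        "stimuli": {
            "f0_lo": 200.0,
            "f0_hi": 600.0,
            "f0_step": 20.0,
            "n_harmonics": 10,
            "irn_iterations": 30,
            "level_db_spl": 50.0,
            "duration": 0.2,
            "ramp": 0.01,
            "sample_rate": 50_000.0,
        },
        "frontend": {
            "n_anf": 2500,
            "cf_lo": 125.0,
            "cf_hi": 20_000.0,
            "compression": 0.3,
            "normalization": "l2",
        },
        "network": {
            "n_out": 200,
            "learning_rate": 0.25,
            "slope": 17.45,
            "sparseness": 0.10,
            "epochs": 50,
        },
        "experiment": {
            "random_decay_epochs": 100,
            "decode_tolerance_hz": 20.0,
            "binarize_threshold": 0.5,
        },
    }


def _deep_update(base: dict, override: dict) -> dict:
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML override file."""
    cfg = copy.deepcopy(default_config())
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        _deep_update(cfg, override)
    return cfg


def resolve_network_params(cfg: dict, *, seed: int | None = None) -> NetworkParams:
    net = cfg["network"]
    return NetworkParams(
        n_in=cfg["frontend"]["n_anf"],
        n_out=net["n_out"],
        learning_rate=net["learning_rate"],
        slope=net["slope"],
        sparseness=net["sparseness"],
        epochs=net["epochs"],
        seed=seed,
    )


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
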