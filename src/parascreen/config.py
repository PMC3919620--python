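"""Flat key-value configuration files (YAML) for the simulator and CLI."""

from __future__ import annotations

import yaml

#: every simulator parameter with its default, also the config schema
SIMULATE_DEFAULTS: dict = {
    "n_clones": 10000,
    "skew_sd": 1.5,
    "parasite_fraction": 0.001,
    "parasite_advantage": 10.0,
    "growth_sd": 0.1,
    "mode": "bulk",
    "rounds": 1,
    "loading_noise_cv": 0.2,
    "n_reads": 100000,
    "dispersion_factor": 1.0,
    "barcode": "ACGTAC",
    "flank5": "TCTCACTCC",
    "flank3": "GGTGGAGGA",
    "barcode_error_rate": 0.02,
    "phred_pass_rate": 0.60,
    "nnk_violation_rate": 0.20,
    "point_mutation_rate": 0.01,
    "fr_split": 0.5,
    "quality_cut": 30,
    "seed": 0,
}


def load_config(path, defaults: dict | None = None) -> dict:
    """Load a flat mapping config, layered over ``defaults``."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict) or any(isinstance(v, (dict, list)) for v in data.values()):
        raise ValueError("config must be a flat key-value mapping")
    out = dict(defaults or {})
    unknown = set(data) - set(out) if defaults else set()
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out.update(data)
    return out


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
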