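"""Pipeline configuration: one YAML file, nested sections, CLI overrides.

A config either names input files (``inputs:``) or requests a simulation
(``simulation:``).  Every stage parameter has a key here and a matching CLI
flag; unspecified keys fall back to the defaults below.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .datamodel import ValidationError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "out",
    "stages": ["multifunctionality", "rarity", "stoichiometry", "guilds", "stats"],
    "inputs": {},      # function_matrix, plot_metadata, otu_bacteria, otu_fungi, guild_map
    "simulation": None,  # SimulationConfig overrides; {} uses all defaults
    "dialect": "tsv",
    "multifunctionality": {
        "single_thresholds": [0.25, 0.50, 0.75, 0.90],
        "grid": "5:99:1",          # percent start:stop:step, inclusive
        "alpha": 0.05,
        "top_fraction": 0.05,
        "shift_nonneg": False,
        "drop_constant": False,
    },
    "rarity": {"abundant": 0.01, "rare": 0.0001},
    "stoichiometry": {"units": "nmol_g_h", "sqrt": True},
    "stats": {"gate_alpha": 0.05, "welch": False},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config, merge onto defaults, then apply overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    stages = cfg.get("stages") or []
    known = {"multifunctionality", "rarity", "stoichiometry", "guilds", "stats"}
    unknown = set(stages) - known
    if unknown:
        raise ValidationError(f"unknown stage(s): {', '.join(sorted(unknown))}")
    simulated = cfg.get("simulation") is not None
    inputs = cfg.get("inputs") or {}
    if not simulated:
        if "function_matrix" not in inputs:
            raise ValidationError("config needs either a simulation block or inputs.function_matrix")
        if "rarity" in stages and not ({"otu_bacteria", "otu_fungi"} & set(inputs)):
            raise ValidationError("rarity stage requires otu table (inputs.otu_bacteria or inputs.otu_fungi)")
        if "guilds" in stages and ("otu_fungi" not in inputs or "guild_map" not in inputs):
            raise ValidationError("guilds stage requires inputs.otu_fungi and inputs.guild_map")
        if "stats" in stages and "plot_metadata" not in inputs:
            raise ValidationError("stats stage requires inputs.plot_metadata")
    mf = cfg["multifunctionality"]
    for t in mf["single_thresholds"]:
        if not 0 < t < 1:
            raise ValidationError(f"single threshold {t} outside (0, 1)")
    parse_grid(mf["grid"])


def parse_grid(spec) -> list[float]:
    """Parse a ``start:stop:step`` percent grid (inclusive) to fractions."""
    if isinstance(spec, (list, tuple)):
        vals = [float(v) for v in spec]
    else:
        try:
            start, stop, step = (int(x) for x in str(spec).split(":"))
        except ValueError:
            raise ValidationError(f"bad grid spec {spec!r}; expected 'start:stop:step' in percent") from None
        if step <= 0 or stop < start or start <= 0 or stop >= 100:
            raise ValidationError(f"bad grid spec {spec!r}")
        vals = [k / 100 for k in range(start, stop + 1, step)]
    if any(not 0 < v < 1 for v in vals):
        raise ValidationError("grid thresholds must lie in (0, 1)")
    return vals


def config_hash(cfg: dict) -> str:
    """Stable hash of the resolved configuration, for the run log."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
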