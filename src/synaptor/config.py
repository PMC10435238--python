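"""YAML configuration for conditions, parameter overrides and run settings.

Config layout::

    conditions:
      age_days: 50
      temperature_C: 35
      ca_o_mM: 2.5
      mg_o_mM: 1.3
      d_soma_um: 200
      dye_mode: false
      evoked_ap: false
      forced_release: false
      deterministic_sources: []   # subset of presyn/ampa/nmda/gaba/vgcc/plasticity
    parameters:            # optional per-symbol overrides (sensitivity studies)
      gamma_Na: 900
    run:                   # optional run settings for the CLI
      n_samples: 100
      seed: 7
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple

import yaml

from .conditions import ExperimentalConditions
from .params import default_params

__all__ = ["load_conditions", "dump_conditions"]

_KEYMAP = {
    "age_days": "age",
    "temperature_C": "temperature",
    "ca_o_mM": "ca_o",
    "mg_o_mM": "mg_o",
    "d_soma_um": "d_soma",
    "dye_mode": "dye_mode",
    "evoked_ap": "evoked_ap_enabled",
    "forced_release": "forced_release",
    "deterministic_sources": "deterministic_sources",
}


def load_conditions(path: str | Path) -> Tuple[ExperimentalConditions, Dict]:
    """Read a config file; returns (conditions, run-settings dict)."""
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    kwargs = {}
    for key, value in (doc.get("conditions") or {}).items():
        if key not in _KEYMAP:
            raise KeyError(f"unknown conditions key {key!r}")
        kwargs[_KEYMAP[key]] = value
    params = default_params()
    overrides = doc.get("parameters") or {}
    if overrides:
        params = params.replace(**overrides)
    kwargs["params"] = params
    if "deterministic_sources" in kwargs:
        kwargs["deterministic_sources"] = frozenset(kwargs["deterministic_sources"])
    return ExperimentalConditions(**kwargs), (doc.get("run") or {})


def dump_conditions(cond: ExperimentalConditions, path: str | Path) -> None:
    """Write a conditions block (not the full parameter table) to YAML."""
    inv = {v: k for k, v in _KEYMAP.items()}
    block = {
        inv["age"]: cond.age,
        inv["temperature"]: cond.temperature,
        inv["ca_o"]: cond.ca_o,
        inv["mg_o"]: cond.mg_o,
        inv["d_soma"]: cond.d_soma,
        inv["dye_mode"]: cond.dye_mode,
        inv["evoked_ap_enabled"]: cond.evoked_ap_enabled,
        inv["forced_release"]: cond.forced_release,
        inv["deterministic_sources"]: sorted(cond.deterministic_sources),
    }
    changed = {k: v for k, v in cond.params.items()
               if default_params()[k] != v}
    doc = {"conditions": block}
    if changed:
        doc["parameters"] = changed
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)
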