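"""Parameter defaults and plain-YAML configuration I/O.

Two kinds of constants live here.  Values printed in the primary
literature on *Crocosphaera* combined-N uptake (maximum NH4+ uptake of
6.6 d^-1 for Crocosphaera and 1.1 d^-1 for other phytoplankton; the
0.31 d^-1 diazotrophic growth floor) are used as-is.  Everything else —
half-saturation constants, NO3- maxima, mortality, zooplankton
parameters, ecosystem initial conditions — are package defaults chosen
to be consistent with the qualitative behaviour those sources report
(Crocosphaera has the higher NO3- uptake maximum but also the higher
NH4+ half-saturation, so it wins at high N and loses, without fixation,
at ~1 nM).  They are all overridable through the config file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .model_core import EcosystemState, PhytoGroupParams, ZooParams

__all__ = [
    "DEFAULT_CRO",
    "DEFAULT_OTH",
    "DEFAULT_ZOO",
    "DEFAULT_ECOSYSTEM_STATE",
    "default_config",
    "load_config",
    "save_config",
    "groups_from_config",
    "zoo_from_config",
    "config_hash",
]

#: Crocosphaera: high uptake maxima, high half-saturation, fixation floor.
DEFAULT_CRO = PhytoGroupParams(
    name="Cro",
    vmax_nh4=6.6,
    vmax_no3=3.0,
    k_nh4=500.0,
    k_no3=500.0,
    mortality=0.1,
    diazotroph_floor=0.31,
)

#: Aggregate of other phytoplankton: lower maxima, higher affinity.
DEFAULT_OTH = PhytoGroupParams(
    name="Oth",
    vmax_nh4=1.1,
    vmax_no3=0.8,
    k_nh4=50.0,
    k_no3=100.0,
    mortality=0.1,
    diazotroph_floor=None,
)

DEFAULT_ZOO = ZooParams(g_max=1.0, k_g=5.0, m_zoo=0.1)

DEFAULT_ECOSYSTEM_STATE = EcosystemState(n_cro=1.0, n_oth=1.0, n_zoo=0.1)


def _group_dict(params: PhytoGroupParams) -> dict[str, Any]:
    d = asdict(params)
    d.pop("name")
    if d["diazotroph_floor"] is None:
        d.pop("diazotroph_floor")
    return d


def default_config() -> dict[str, Any]:
    """The full default configuration as a plain nested dict."""
    return {
        "groups": {
            DEFAULT_CRO.name: _group_dict(DEFAULT_CRO),
            DEFAULT_OTH.name: _group_dict(DEFAULT_OTH),
        },
        "zoo": asdict(DEFAULT_ZOO),
        "ecosystem": {
            "initial": {
                "n_cro": DEFAULT_ECOSYSTEM_STATE.n_cro,
                "n_oth": DEFAULT_ECOSYSTEM_STATE.n_oth,
                "n_zoo": DEFAULT_ECOSYSTEM_STATE.n_zoo,
            },
            "t_end": 10.0,
            "dt": 0.01,
        },
        "incubation": {
            "forcing": {"kind": "constant", "nh4": 115.0, "no3": 5.0},
            "initial": {"Cro": 5.0, "Oth": 15.0},
            "t_end": 3.0,
            "dt": 0.01,
        },
        "synthetic": {"seed": 0, "sink_fraction": 0.5, "noise_sigma": 0.1},
        "fit": {
            "group": "Cro",
            "free": {"vmax_nh4": [1.0, 12.0]},
            "n_starts": 5,
            "seed": 0,
        },
        "budget": {"day_start": 0.0, "day_end": 3.0, "mortality": 0.0},
    }


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config file, layered over the package defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(user)}")
    return _deep_merge(default_config(), user)


def save_config(config: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def groups_from_config(config: Mapping[str, Any]) -> dict[str, PhytoGroupParams]:
    """Build PhytoGroupParams for every entry under ``groups``."""
    allowed = {"vmax_nh4", "vmax_no3", "k_nh4", "k_no3", "mortality", "diazotroph_floor"}
    groups: dict[str, PhytoGroupParams] = {}
    for name, fields in config.get("groups", {}).items():
        unknown = set(fields) - allowed
        if unknown:
            raise ConfigurationError(
                f"groups.{name}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}"
            )
        groups[name] = PhytoGroupParams(name=name, **fields)
    return groups


def zoo_from_config(config: Mapping[str, Any]) -> ZooParams:
    fields = config.get("zoo", {})
    allowed = {"g_max", "k_g", "m_zoo"}
    unknown = set(fields) - allowed
    if unknown:
        raise ConfigurationError(f"zoo: unknown keys {sorted(unknown)}")
    merged = {**asdict(DEFAULT_ZOO), **fields}
    return ZooParams(**merged)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable SHA-256 of a config mapping (sorted-key JSON)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
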