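"""Flat key-value run configuration files.

Config files are plain YAML mappings whose keys mirror the model's
parameter names (TMax, RMax, N, M or M_fraction, PV, AP, SP, the prior
block, the rule flags and the seed).  Pythonic field names are accepted
too.  Unknown keys are an error, named in the message.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .engine import SimConfig

__all__ = ["KEY_ALIASES", "config_from_mapping", "load_config"]

#: Accepted config keys -> SimConfig field.
KEY_ALIASES = {
    "TMax": "t_max",
    "RMax": "r_max",
    "N": "n_agents",
    "M": "m",
    "M_fraction": "m_fraction",
    "PV": "pv",
    "AP": "ap",
    "SP": "sp",
    "mu_A": "mu_asocial",
    "mu_S": "mu_social",
    "nu": "nu",
    "p0": "p0",
    "sigma": "sigma",
    "sd_min": "sd_min",
    "attendance_rule": "attendance_rule",
    "transmission_rule": "transmission_rule",
    "positivity_strict": "positivity_strict",
    "pv_is_variance": "pv_is_variance",
    "seed": "seed",
    "condition_id": "condition_id",
}
_FIELDS = set(SimConfig.__dataclass_fields__)


def config_from_mapping(
    mapping: Mapping[str, Any], overrides: Optional[Mapping[str, Any]] = None
) -> SimConfig:
    """Build a SimConfig from flat keys; ``overrides`` win over the file.

    Raises ValueError naming the first unknown key encountered.
    """
    kwargs: dict[str, Any] = {}
    for source in (mapping, overrides or {}):
        for key, value in source.items():
            if value is None:
                continue
            field = KEY_ALIASES.get(key, key if key in _FIELDS else None)
            if field is None:
                raise ValueError(f"unknown configuration key: {key!r}")
            kwargs[field] = value
    # An explicit prior spread replaces the calibration target and vice versa.
    if "sigma" in kwargs and "p0" not in kwargs:
        kwargs["p0"] = None
    if "p0" in kwargs and "sigma" not in kwargs:
        kwargs["sigma"] = None
    return SimConfig(**kwargs)


def load_config(
    path: Union[str, Path, None], overrides: Optional[Mapping[str, Any]] = None
) -> SimConfig:
    """Read a YAML config file (optional) and apply command-line overrides."""
    mapping: Mapping[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a flat key-value mapping")
        mapping = loaded
    return config_from_mapping(mapping, overrides)
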