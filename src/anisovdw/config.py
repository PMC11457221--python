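"""TOML / YAML configuration files for the command line.

A config file may override the shipped geometry constants and grid protocol::

    [vdw_radii]
    I = 1.98
    He = 1.40

    [bond_lengths]
    I = 1.6092          # H-I covalent distance

    [water]
    oh_length = 0.9572
    hoh_angle = 104.52

    [grid]
    spacing = 0.1

    [probe]
    element = "He"

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["load_config"]

_KNOWN_SECTIONS = {"vdw_radii", "bond_lengths", "water", "grid", "probe"}


def load_config(path) -> dict:
    """Load a TOML (.toml) or YAML (.yml/.yaml) config file and validate keys."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix in (".yml", ".yaml"):
        data = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValidationError(f"unsupported config extension {path.suffix!r}; use .toml or .yaml")
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(data) - _KNOWN_SECTIONS
    if unknown:
        raise ValidationError(f"unknown config sections {sorted(unknown)}; known: {sorted(_KNOWN_SECTIONS)}")
    return data
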