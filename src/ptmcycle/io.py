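"""Config-file round-tripping and the bundled reference parameter sets.

Parameter sets travel as flat key -> value YAML mappings whose keys are
named exactly like the :class:`~ptmcycle.single_site.RateConstants` fields.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import asdict
from pathlib import Path

import yaml

from .single_site import RateConstants

__all__ = [
    "load_rate_constants",
    "save_rate_constants",
    "reference_parameters",
    "REFERENCE_REGIMES",
]

REFERENCE_REGIMES = ("unsaturated", "saturated_Q", "saturated_KM")


def load_rate_constants(path: str | Path) -> RateConstants:
    """Read a flat YAML mapping into a :class:`RateConstants`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key -> value mapping")
    unknown = set(raw) - set(RateConstants.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return RateConstants(**{k: float(v) for k, v in raw.items()})


def save_rate_constants(params: RateConstants, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in asdict(params).items()}, fh,
                       sort_keys=False)


def reference_parameters(regime: str = "unsaturated") -> RateConstants:
    """The bundled reference parameter set for a saturation regime.

    ``unsaturated`` (K_M = 10 x [S]_T), ``saturated_Q`` (saturation via a
    100-fold higher synthesis rate) or ``saturated_KM`` (saturation via a
    100-fold lower Michaelis constant).
    """
    if regime not in REFERENCE_REGIMES:
        raise ValueError(f"regime must be one of {REFERENCE_REGIMES}")
    ref = importlib.resources.files("ptmcycle").joinpath("data/table1.yaml")
    raw = yaml.safe_load(ref.read_text())
    return RateConstants(**{k: float(v) for k, v in raw[regime].items()})
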