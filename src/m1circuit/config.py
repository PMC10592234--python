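"""Model configuration: structured-text (YAML) loading and validation.

All quantitative model data — cylinder dimensions, layer boundaries and
densities, class ratios, synapse kinetics, long-range budgets and condition
presets — live in configuration, never in code.  :func:`default_config`
returns the packaged fixture configuration.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a model configuration is inconsistent."""


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a model configuration from a YAML file and validate it."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def default_config() -> dict[str, Any]:
    """The packaged default model configuration (deep copy, safe to mutate)."""
    ref = resources.files("m1circuit.data").joinpath("default_model.yaml")
    cfg = yaml.safe_load(ref.read_text())
    validate_config(cfg)
    return copy.deepcopy(cfg)


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Check structural invariants; raise :class:`ConfigurationError` if violated."""
    for block in ("cylinder", "layers", "ratios"):
        if block not in cfg:
            raise ConfigurationError(f"missing config block {block!r}")
    layers = cfg["layers"]
    prev_hi = 0.0
    for spec in layers:
        lo, hi = float(spec["ncd_lo"]), float(spec["ncd_hi"])
        if not lo < hi:
            raise ConfigurationError(f"layer {spec['name']}: ncd_lo must be < ncd_hi")
        if abs(lo - prev_hi) > 1e-9:
            raise ConfigurationError(
                f"layer {spec['name']}: layers must tile [0,1] without gaps/overlap"
            )
        if float(spec["density_per_mm3"]) < 0:
            raise ConfigurationError(f"layer {spec['name']}: negative density")
        prev_hi = hi
    if abs(prev_hi - 1.0) > 1e-9:
        raise ConfigurationError("layers must end at NCD = 1 (white matter)")
    for layer, row in cfg["ratios"].items():
        total = sum(float(v) for v in row.values())
        if abs(total - 1.0) > 1e-3:
            raise ConfigurationError(f"ratio row for {layer} sums to {total}, not 1")
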