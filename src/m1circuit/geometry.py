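"""Cylindrical tissue geometry and normalized-cortical-depth soma placement.

The modeled volume is a cylinder of cortical tissue (default 300 um diameter,
1350 um deep).  Depth is measured in normalized cortical depth (NCD): 0 at
the pia, 1 at the white matter.  Layers tile [0, 1]; per-layer neuron counts
come from layer volume x density, partitioned across cell classes by a ratio
table, and somata are placed uniformly at random within each layer's slab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .streams import substream

__all__ = [
    "LayerSpec",
    "PopulationSpec",
    "CellLocation",
    "build_geometry",
    "ncd_of_depth",
    "layer_of_ncd",
    "layer_counts",
    "layers_from_config",
]


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer: an NCD slab with a density and an E/I split."""

    name: str
    ncd_lo: float
    ncd_hi: float
    density: float  # neurons / mm^3
    exc_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.ncd_lo < self.ncd_hi:
            raise ConfigurationError(f"layer {self.name}: ncd_lo >= ncd_hi")
        if self.density < 0:
            raise ConfigurationError(f"layer {self.name}: negative density")

    @property
    def thickness_ncd(self) -> float:
        return self.ncd_hi - self.ncd_lo


@dataclass(frozen=True)
class PopulationSpec:
    """A model population: one cell class within an NCD span."""

    name: str
    cell_class: str  # IT, PT, CT, PV or SOM
    ncd_lo: float
    ncd_hi: float
    count: int
    template_ref: str = ""

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigurationError(f"population {self.name}: negative count")


@dataclass(frozen=True)
class CellLocation:
    """Soma position of one cell; x, y, depth in um, plus dimensionless NCD."""

    cell_id: int
    x: float
    y: float
    depth: float
    ncd: float


def ncd_of_depth(depth: float, total_depth: float) -> float:
    """Normalized cortical depth of a point ``depth`` um below the pia."""
    if not 0.0 <= depth <= total_depth:
        raise ValueError(f"depth {depth} outside [0, {total_depth}]")
    return depth / total_depth


def layer_of_ncd(ncd: float, layers: Sequence[LayerSpec]) -> str:
    """Name of the layer containing ``ncd``.

    Layer intervals are half-open [lo, hi); an NCD exactly on an interior
    boundary belongs to the deeper layer, and NCD = 1 maps to the deepest.
    """
    if not 0.0 <= ncd <= 1.0:
        raise ValueError(f"ncd {ncd} outside [0, 1]")
    ordered = sorted(layers, key=lambda s: s.ncd_lo)
    for spec in ordered:
        if spec.ncd_lo <= ncd < spec.ncd_hi:
            return spec.name
    return ordered[-1].name  # ncd == 1.0


def layers_from_config(cfg: Mapping[str, Any]) -> list[LayerSpec]:
    out = [
        LayerSpec(
            name=s["name"],
            ncd_lo=float(s["ncd_lo"]),
            ncd_hi=float(s["ncd_hi"]),
            density=float(s["density_per_mm3"]),
            exc_fraction=float(s.get("exc_fraction", 0.0)),
        )
        for s in cfg["layers"]
    ]
    _check_tiling(out)
    return out


def _check_tiling(layers: Sequence[LayerSpec]) -> None:
    ordered = sorted(layers, key=lambda s: s.ncd_lo)
    prev = 0.0
    for spec in ordered:
        if abs(spec.ncd_lo - prev) > 1e-9:
            raise ConfigurationError("layers must tile [0,1] without gaps or overlap")
        prev = spec.ncd_hi
    if abs(prev - 1.0) > 1e-9:
        raise ConfigurationError("layers must end at NCD = 1")


def layer_counts(
    layers: Sequence[LayerSpec],
    diameter_um: float,
    depth_um: float,
    scale: float = 1.0,
) -> dict[str, int]:
    """Neurons per layer: round(density x cylinder slab volume x scale).

    Volume is computed in mm^3 from the cylinder cross-section and the
    layer's thickness in um.
    """
    radius_mm = diameter_um / 2.0 / 1000.0
    area_mm2 = math.pi * radius_mm**2
    out = {}
    for spec in layers:
        thickness_mm = spec.thickness_ncd * depth_um / 1000.0
        volume = area_mm2 * thickness_mm
        out[spec.name] = int(round(spec.density * volume * scale))
    return out


def _partition_counts(total: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Round class counts to nearest; assign the residual to the largest class."""
    raw = {k: total * f for k, f in fractions.items()}
    counts = {k: int(round(v)) for k, v in raw.items()}
    residual = total - sum(counts.values())
    if residual != 0:
        largest = max(fractions, key=lambda k: fractions[k])
        counts[largest] += residual
    return counts


def _population_name(cls: str, layer: str) -> str:
    if cls in ("PV", "SOM"):
        return f"{cls}{layer.removeprefix('L')}"
    return cls  # excitatory class names already carry the layer (IT5A, PT5B...)


def build_geometry(
    layers: Sequence[LayerSpec],
    ratios: Mapping[str, Mapping[str, float]],
    cylinder: Mapping[str, float],
    seed: int,
    scale: float = 1.0,
    merge_interneuron_layers: Iterable[Sequence[str]] = (),
    class_templates: Mapping[str, str] | None = None,
) -> tuple[list[PopulationSpec], list[CellLocation], pd.DataFrame]:
    """Instantiate populations and soma positions.

    Per-layer counts are density x slab volume (rounded), split across
    classes by the per-layer ratio rows (rows must sum to 1); somata are
    placed uniformly at random in each population's cylindrical slab using
    the geometry substream of ``seed``.  Interneuron populations listed in
    ``merge_interneuron_layers`` (by default PV/SOM of L4 + L5A) are merged
    into a single population spanning both layers.

    Returns (populations, locations, cell table).  The cell table has one
    row per cell: cell_id, pop, cell_class, x, y, depth, ncd.
    """
    _check_tiling(layers)
    for layer, row in ratios.items():
        if abs(sum(row.values()) - 1.0) > 1e-3:
            raise ConfigurationError(f"ratio row for {layer} does not sum to 1")

    diameter = float(cylinder["diameter_um"])
    depth_total = float(cylinder["depth_um"])
    per_layer = layer_counts(layers, diameter, depth_total, scale=scale)
    by_name = {s.name: s for s in layers}

    # (class, span, layer list) -> count; merged interneuron spans pool
    # counts across their member layers.
    merge_lookup: dict[str, tuple[str, ...]] = {}
    for group in merge_interneuron_layers:
        for member in group:
            merge_lookup[member] = tuple(group)

    pop_counts: dict[tuple[str, tuple[str, ...]], int] = {}
    for layer_name, row in ratios.items():
        if layer_name not in by_name:
            raise ConfigurationError(f"ratio row for unknown layer {layer_name}")
        split = _partition_counts(per_layer.get(layer_name, 0), dict(row))
        for cls, n in split.items():
            if cls in ("PV", "SOM") and layer_name in merge_lookup:
                span_layers = merge_lookup[layer_name]
            else:
                span_layers = (layer_name,)
            key = (cls, span_layers)
            pop_counts[key] = pop_counts.get(key, 0) + n

    populations: list[PopulationSpec] = []
    for (cls, span_layers), count in pop_counts.items():
        lo = min(by_name[l].ncd_lo for l in span_layers)
        hi = max(by_name[l].ncd_hi for l in span_layers)
        label_layer = span_layers[-1] if cls in ("PV", "SOM") else span_layers[0]
        name = _population_name(cls, label_layer)
        cell_class = cls if cls in ("PV", "SOM") else cls  # IT/PT/CT keep class
        full_name = name if cls in ("PV", "SOM") else f"{cls}{label_layer.removeprefix('L')}"
        tref = ""
        if class_templates:
            tref = class_templates.get(full_name, class_templates.get(cls, ""))
        populations.append(
            PopulationSpec(
                name=full_name,
                cell_class=cls,
                ncd_lo=lo,
                ncd_hi=hi,
                count=count,
                template_ref=tref,
            )
        )
    populations.sort(key=lambda p: (p.ncd_lo, p.name))

    rng = substream(seed, "geometry")
    radius = diameter / 2.0
    rows = []
    cell_id = 0
    locations: list[CellLocation] = []
    for pop in populations:
        # uniform in the cylinder cross-section: r = R*sqrt(u)
        u = rng.random(pop.count)
        theta = rng.random(pop.count) * 2.0 * math.pi
        r = radius * np.sqrt(u)
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        ncd = rng.uniform(pop.ncd_lo, pop.ncd_hi, size=pop.count)
        depth = ncd * depth_total
        for i in range(pop.count):
            locations.append(
                CellLocation(cell_id, float(x[i]), float(y[i]), float(depth[i]), float(ncd[i]))
            )
            rows.append((cell_id, pop.name, pop.cell_class, x[i], y[i], depth[i], ncd[i]))
            cell_id += 1

    table = pd.DataFrame(
        rows, columns=["cell_id", "pop", "cell_class", "x", "y", "depth", "ncd"]
    )
    return populations, locations, table
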