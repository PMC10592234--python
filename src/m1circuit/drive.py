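"""Long-range input: seven source regions of Poisson spike generators.

Each region (PO, VL=MTh, S1, S2, cM1, M2, OC) is a population of 1000
independent Poisson units whose rates are drawn uniformly per unit from a
state-dependent range (0-5 Hz spontaneous, 0-10 Hz for increased drive).
Convergence (synaptic inputs per postsynaptic cell) follows a budget
derived from the average 8234 synaptic contacts per cell: 80% excitatory of
which 80% long-range, and 20% inhibitory of which 30% long-range; the
excitatory long-range budget is split across regions by configured shares
and weighted by the normalized input strength of each (region, class) pair.
All long-range unitary weights are 0.5 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .streams import child_seed, substream

__all__ = [
    "REGIONS",
    "SynapseBudget",
    "longrange_budget",
    "convergence",
    "assign_rates",
    "poisson_trains",
    "build_longrange_synapses",
]

REGIONS = ("PO", "VL", "S1", "S2", "cM1", "M2", "OC")
# MTh is an accepted alias for VL (motor thalamus).
REGION_ALIASES = {"MTh": "VL"}


def canonical_region(name: str) -> str:
    return REGION_ALIASES.get(name, name)


@dataclass(frozen=True)
class SynapseBudget:
    """Average per-cell synaptic contact budget and its long-range split."""

    contacts_per_cell: int = 8234
    exc_fraction: float = 0.8
    exc_longrange_fraction: float = 0.8
    inh_longrange_fraction: float = 0.3

    def __post_init__(self) -> None:
        for f in (self.exc_fraction, self.exc_longrange_fraction,
                  self.inh_longrange_fraction):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("budget fractions must be in [0, 1]")


def longrange_budget(budget: SynapseBudget) -> tuple[int, int]:
    """Per-cell long-range (excitatory, inhibitory) contact counts."""
    exc = round(budget.contacts_per_cell * budget.exc_fraction
                * budget.exc_longrange_fraction)
    inh = round(budget.contacts_per_cell * (1.0 - budget.exc_fraction)
                * budget.inh_longrange_fraction)
    return int(exc), int(inh)


def convergence(
    region_max_inputs: float, normalized_strength: float
) -> int:
    """Synaptic inputs per cell for one projection: max inputs x strength."""
    if not 0.0 <= normalized_strength <= 1.0:
        raise ValueError("normalized strength must be in [0, 1]")
    return int(round(region_max_inputs * normalized_strength))


def assign_rates(
    region: str,
    rate_range: tuple[float, float],
    n_units: int,
    seed: int,
) -> np.ndarray:
    """Per-unit rates ~ U(lo, hi), fixed for the run (input stream of seed)."""
    lo, hi = rate_range
    if not 0.0 <= lo <= hi:
        raise ValueError("rate range must satisfy 0 <= lo <= hi")
    rng = substream(seed, "rates")
    # independent per region: fold the region tag into the draw position
    idx = REGIONS.index(canonical_region(region)) if canonical_region(region) in REGIONS else len(REGIONS)
    all_rates = rng.uniform(0.0, 1.0, size=(len(REGIONS) + 1, n_units))
    return lo + (hi - lo) * all_rates[idx]


def poisson_trains(
    rates_hz: Sequence[float],
    duration_ms: float,
    seed: int,
    unit_offset: int = 0,
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per unit.

    Reproducible per (seed, unit_offset + index): each unit draws from its
    own child stream, so trains are invariant to which other units exist.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    out = []
    for i, rate in enumerate(rates_hz):
        if rate <= 0:
            out.append(np.empty(0))
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(0x747261, unit_offset + i))
        )
        n_expected = rate * duration_ms / 1000.0
        n = rng.poisson(n_expected)
        times = np.sort(rng.uniform(0.0, duration_ms, size=n))
        out.append(times)
    return out


def build_longrange_synapses(
    cells: pd.DataFrame,
    cell_template: Mapping[int, str],
    templates: Mapping[str, Any],
    democracy_maps: Mapping[str, Any],
    config: Mapping[str, Any],
    seed: int,
    profiles: Mapping[tuple[str, str], Any] | None = None,
) -> pd.DataFrame:
    """Structural long-range wiring: unit-to-target contacts per region.

    For each cell and region, the convergence count is drawn from the
    budget arithmetic (region share x normalized strength for the cell's
    class, scaled by the global convergence scale); source units are chosen
    uniformly at random among the region's 1000 generators (without
    replacement when the count allows).  An additional generic inhibitory
    source carries the long-range inhibitory budget with fast GABA_A
    kinetics.  Contacts land on dendrites via the projection's radial
    profile when available, else uniformly by dendritic length.
    """
    from .synapses import _comp_for_radial_position, _dendritic_comps

    rng = substream(seed, "longrange")
    lr_cfg = config["longrange"]
    n_units = int(lr_cfg["n_units"])
    weight_mv = float(lr_cfg["weight_mv"])
    scale = float(lr_cfg.get("convergence_scale", 1.0))
    budget = SynapseBudget(
        contacts_per_cell=int(lr_cfg["budget"]["contacts_per_cell"]),
        exc_fraction=float(lr_cfg["budget"]["exc_fraction"]),
        exc_longrange_fraction=float(lr_cfg["budget"]["exc_longrange_fraction"]),
        inh_longrange_fraction=float(lr_cfg["budget"]["inh_longrange_fraction"]),
    )
    exc_budget, inh_budget = longrange_budget(budget)
    shares = lr_cfg["region_shares"]
    strengths = lr_cfg["normalized_strength"]
    delay_ms = float(config["wiring"]["delay_base_ms"])
    profiles = profiles or {}

    rows: list[tuple] = []
    for cell in cells.itertuples():
        tname = cell_template[cell.cell_id]
        tpl = templates[tname]
        dmap = democracy_maps[tname]
        pool = _dendritic_comps(tpl)
        lens = np.array([tpl.compartments[c].length for c in pool])
        lens = lens / lens.sum()
        cls_key = cell.pop if cell.pop in strengths.get("PO", {}) else cell.cell_class
        for region in REGIONS:
            share = float(shares.get(region, 0.0))
            strength = float(strengths.get(region, {}).get(cls_key, 0.0))
            n_contacts = convergence(exc_budget * share * scale, strength)
            if n_contacts <= 0:
                continue
            if n_contacts <= n_units:
                units = rng.choice(n_units, size=n_contacts, replace=False)
            else:
                units = rng.integers(0, n_units, size=n_contacts)
            prof = profiles.get((region, tpl.class_name))
            if prof is not None:
                nb = len(prof.weights)
                bins = rng.choice(nb, size=n_contacts, p=prof.weights)
                pos = (bins + rng.random(n_contacts)) / nb
                comps = _comp_for_radial_position(tpl, pos)
            else:
                comps = pool[rng.choice(len(pool), size=n_contacts, p=lens)]
            for u, comp in zip(units, comps):
                g_full = dmap.weight_to_g(weight_mv, int(comp))
                rows.append((region, int(u), cell.cell_id, int(comp), "AMPA",
                             weight_mv / 2, g_full / 2, delay_ms))
                rows.append((region, int(u), cell.cell_id, int(comp), "NMDA",
                             weight_mv / 2, g_full / 2, delay_ms))
        # generic long-range inhibitory source
        n_inh = int(round(inh_budget * scale))
        if n_inh > 0:
            units = (rng.choice(n_units, size=n_inh, replace=False)
                     if n_inh <= n_units else rng.integers(0, n_units, size=n_inh))
            comps = pool[rng.choice(len(pool), size=n_inh, p=lens)]
            for u, comp in zip(units, comps):
                g_full = dmap.weight_to_g(weight_mv, int(comp))
                rows.append(("INH", int(u), cell.cell_id, int(comp),
                             "GABAA_fast", weight_mv, g_full, delay_ms))

    return pd.DataFrame(
        rows,
        columns=["region", "unit", "post_id", "comp", "receptor",
                 "weight_mv", "g_us", "delay_ms"],
    )
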