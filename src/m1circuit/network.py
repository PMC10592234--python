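"""The fully instantiated circuit: populations, somata, templates, synapses.

:class:`NetworkModel` is the in-memory container passed to the engine.  It is
assembled by :func:`m1circuit.scenarios.build_fixture_network` (geometry ->
cells -> wiring -> synapses -> drive) and carries everything the integrator
and the observables need: per-cell template references and coordinates, the
local synapse table, and the long-range source descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import CellLocation, PopulationSpec


@dataclass
class NetworkModel:
    """Populations, soma positions, cell templates and the synapse tables."""

    config: Mapping[str, Any]
    populations: Sequence[PopulationSpec]
    cells: pd.DataFrame  # cell_id, pop, cell_class, x, y, depth, ncd
    templates: Mapping[str, Any]  # template name -> CellTemplate
    cell_template: Mapping[int, str]  # cell_id -> template name
    connections: pd.DataFrame | None = None  # local edge list
    synapses: pd.DataFrame | None = None  # local synaptic contacts
    longrange: Mapping[str, Any] = field(default_factory=dict)
    longrange_synapses: pd.DataFrame | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def cells_of(self, pop: str) -> np.ndarray:
        """Cell ids of one population ('PT5B_upper'/'PT5B_lower' split by NCD)."""
        if pop in ("PT5B_upper", "PT5B_lower"):
            spec = self.population("PT5B")
            mid = 0.5 * (spec.ncd_lo + spec.ncd_hi)
            sub = self.cells[self.cells["pop"] == "PT5B"]
            if pop == "PT5B_upper":
                sub = sub[sub["ncd"] < mid]
            else:
                sub = sub[sub["ncd"] >= mid]
            return sub["cell_id"].to_numpy()
        return self.cells.loc[self.cells["pop"] == pop, "cell_id"].to_numpy()

    def population_names(self, split_pt5b: bool = False) -> list[str]:
        names = [p.name for p in self.populations]
        if split_pt5b and "PT5B" in names:
            i = names.index("PT5B")
            names[i : i + 1] = ["PT5B_upper", "PT5B_lower"]
        return names
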