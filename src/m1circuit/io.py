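"""Export helpers: cell tables, edge lists, synapse tables, results.

Everything tabular goes through pandas CSV; simulation results are written
as HDF5 with a CSV spike-table mirror and the run configuration echoed into
the file attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "write_cells_csv",
    "write_edges_csv",
    "write_synapses_csv",
    "population_probability_matrix",
    "save_result",
    "load_result_spikes",
    "write_trains_csv",
]


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def write_edges_csv(connections: pd.DataFrame, path) -> None:
    connections.to_csv(path, index=False)


def write_synapses_csv(synapses: pd.DataFrame, path) -> None:
    synapses.to_csv(path, index=False)


def population_probability_matrix(network) -> pd.DataFrame:
    """Empirical connection probability per (pre pop, post pop).

    The population-level summary of the depth-resolved wiring: realized
    connections divided by the number of ordered pre x post pairs.
    """
    cells = network.cells
    counts = cells.groupby("pop").size()
    conn = network.connections
    pop_of = cells.set_index("cell_id")["pop"]
    pairs = (
        conn.assign(pre_pop=conn["pre_id"].map(pop_of), post_pop=conn["post_id"].map(pop_of))
        .groupby(["pre_pop", "post_pop"], observed=True)
        .size()
    )
    rows = []
    for (pre, post), n in pairs.items():
        denom = counts[pre] * counts[post] - (counts[pre] if pre == post else 0)
        rows.append({"pre_pop": pre, "post_pop": post, "p_con": n / max(denom, 1)})
    return pd.DataFrame(rows).pivot(index="pre_pop", columns="post_pop", values="p_con").fillna(0.0)


def save_result(result, path, write_currents: bool = True) -> None:
    """Write a SimulationResult as HDF5 (+ CSV spike mirror alongside)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("spikes", data=result.spikes)
        fh.create_dataset("voltage_t", data=result.voltage_t)
        fh.create_dataset("voltages", data=result.voltages)
        if write_currents:
            fh.create_dataset("currents", data=result.currents, compression="gzip")
            fh.create_dataset("current_t", data=result.current_t)
        fh.attrs["config"] = json.dumps(dataclasses.asdict(result.config), default=list)
        for k, v in result.meta.items():
            fh.attrs[f"meta_{k}"] = json.dumps(v, default=str)
    result.spike_frame().to_csv(path.with_suffix(".spikes.csv"), index=False)
    result.comp_table.to_csv(path.with_suffix(".comps.csv"), index=False)


def load_result_spikes(path) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["spikes"][...]


def write_trains_csv(trains: dict[int, np.ndarray] | list[np.ndarray], path) -> None:
    """Long-range generated trains as (unit, spike_time_ms) rows."""
    items = trains.items() if isinstance(trains, dict) else enumerate(trains)
    rows = [(u, t) for u, ts in items for t in ts]
    pd.DataFrame(rows, columns=["unit", "spike_time_ms"]).to_csv(path, index=False)
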