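"""SWC morphology reader, used to derive reduced-tree dimensions.

The full reconstructions behind the detailed cell classes are distributed
as SWC files (NeuroMorpho archive "Suter_Shepherd").  The package does not
integrate the full morphologies; this reader imports them for geometry
only: total dendritic length per section type, the apical extent, and the
radial (depth-axis) dendritic-length profile used to build synaptic
density functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["read_swc", "section_lengths", "radial_length_profile", "reduced_dimensions"]

# SWC structure-type codes
_TYPES = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}

_COLUMNS = ["n", "type", "x", "y", "z", "radius", "parent"]


def read_swc(path_or_buffer) -> pd.DataFrame:
    """Parse an SWC file into a point table with segment lengths.

    Returns a frame with columns n, type, section (soma/axon/basal/apical/
    other), x, y, z, radius, parent and seg_length (distance to the parent
    point; 0 for roots).
    """
    frame = pd.read_csv(
        path_or_buffer, sep=r"\s+", comment="#", names=_COLUMNS, header=None
    )
    frame["section"] = frame["type"].map(_TYPES).fillna("other")
    by_id = frame.set_index("n")
    seg = np.zeros(len(frame))
    for i, row in enumerate(frame.itertuples()):
        if row.parent >= 0 and row.parent in by_id.index:
            p = by_id.loc[row.parent]
            seg[i] = float(
                np.sqrt((row.x - p.x) ** 2 + (row.y - p.y) ** 2 + (row.z - p.z) ** 2)
            )
    frame["seg_length"] = seg
    return frame


def section_lengths(swc: pd.DataFrame) -> pd.Series:
    """Total cable length (um) per section type."""
    return swc.groupby("section")["seg_length"].sum()


def radial_length_profile(swc: pd.DataFrame, n_bins: int = 10, axis: str = "y") -> np.ndarray:
    """Dendritic length per normalized radial (depth-axis) bin.

    The radial axis is the coordinate along ``axis`` relative to the soma,
    normalized to the maximum apical extent; only dendritic sections count.
    Returns bin weights normalized to sum 1.
    """
    dend = swc[swc["section"].isin(["basal", "apical"])]
    soma = swc[swc["section"] == "soma"]
    origin = float(soma[axis].mean()) if len(soma) else 0.0
    coord = (dend[axis] - origin).abs()
    extent = float(coord.max())
    if extent <= 0 or len(dend) == 0:
        return np.full(n_bins, 1.0 / n_bins)
    pos = np.clip(coord / extent, 0, 1 - 1e-9)
    weights = np.zeros(n_bins)
    np.add.at(weights, (pos * n_bins).astype(int), dend["seg_length"].to_numpy())
    total = weights.sum()
    return weights / total if total > 0 else np.full(n_bins, 1.0 / n_bins)


@dataclass(frozen=True)
class ReducedDimensions:
    """Summary used to size a reduced few-compartment tree."""

    soma_length: float
    apical_extent: float
    total_basal_length: float
    total_apical_length: float
    total_axon_length: float


def reduced_dimensions(swc: pd.DataFrame, axis: str = "y") -> ReducedDimensions:
    lengths = section_lengths(swc)
    soma = swc[swc["section"] == "soma"]
    apical = swc[swc["section"] == "apical"]
    origin = float(soma[axis].mean()) if len(soma) else 0.0
    extent = float((apical[axis] - origin).abs().max()) if len(apical) else 0.0
    soma_len = float(
        (soma[axis].max() - soma[axis].min()) if len(soma) > 1 else 2.0 * soma["radius"].mean()
        if len(soma)
        else 0.0
    )
    return ReducedDimensions(
        soma_length=soma_len,
        apical_extent=extent,
        total_basal_length=float(lengths.get("basal", 0.0)),
        total_apical_length=float(lengths.get("apical", 0.0)),
        total_axon_length=float(lengths.get("axon", 0.0)),
    )
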