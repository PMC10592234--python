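"""Local connectivity from depth-resolved connection-strength matrices.

Excitatory connection strength s_con (mV) is defined as the product of
connection probability p_con and unitary somatic EPSP amplitude v_con (mV):
s_con = p_con x v_con.  The strength matrices are resolved in normalized
cortical depth (NCD) bands (100/140 um source resolution); v_con comes from
a layerwise unitary-EPSP matrix interpolated onto NCD and clipped to
[0.3, 1.0] mV, and p_con = s_con / v_con (clipped to 1).

Inhibitory connections are confined to the (merged) layer of the presynaptic
interneuron, with probability decaying exponentially with 3-D intersomatic
distance (length constant 100 um) and a Monte-Carlo border correction that
compensates the kernel mass lost outside the cylinder wall.

Connection delays are 2 ms plus distance / 0.5 m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .streams import substream

__all__ = [
    "DecomposedRule",
    "InhibKernel",
    "decompose_strength",
    "interp_vcon",
    "apply_class_adjustments",
    "sample_connections",
    "compute_delay",
    "rules_to_csv",
    "rules_from_csv",
]

RULE_COLUMNS = [
    "pre_class", "pre_lo", "pre_hi", "post_class", "post_lo", "post_hi",
    "s_con", "v_raw",
]


@dataclass(frozen=True)
class DecomposedRule:
    """Probability / unitary-EPSP decomposition of one strength entry."""

    v_con: float  # mV, in [0.3, 1.0]
    p_con: float  # dimensionless, in [0, 1]


@dataclass(frozen=True)
class InhibKernel:
    """Distance kernel for interneuron outputs."""

    length_constant_um: float = 100.0
    base_probability: float = 0.25
    same_layer_only: bool = True
    border_correction: bool = True
    mc_samples: int = 1000

    def __post_init__(self) -> None:
        if self.length_constant_um <= 0:
            raise ConfigurationError("length constant must be positive")


def decompose_strength(
    s_con: float, v_raw: float, clip: tuple[float, float] = (0.3, 1.0)
) -> DecomposedRule:
    """Split s_con into (v_con, p_con): v clipped to [0.3, 1] mV, p = s/v <= 1."""
    if s_con < 0:
        raise ValueError("s_con must be >= 0")
    if v_raw <= 0:
        raise ValueError("v_raw must be > 0")
    v_con = float(min(max(v_raw, clip[0]), clip[1]))
    p_con = float(min(s_con / v_con, 1.0))
    return DecomposedRule(v_con=v_con, p_con=p_con)


def interp_vcon(
    layer_mids: Sequence[float],
    v_matrix: np.ndarray,
    pre_ncd: float | np.ndarray,
    post_ncd: float | np.ndarray,
) -> np.ndarray:
    """Interpolate a layerwise unitary-EPSP matrix onto NCD coordinates.

    Piecewise-linear in both the pre- and post-synaptic NCD on the layer
    midpoints, constant beyond the outermost midpoints.  The result is the
    *raw* v value; clipping to [0.3, 1.0] happens in the decomposition.
    """
    mids = np.asarray(layer_mids, float)
    v = np.asarray(v_matrix, float)
    pre = np.atleast_1d(np.asarray(pre_ncd, float))
    post = np.atleast_1d(np.asarray(post_ncd, float))
    # interp along pre axis for each post column, then along post
    out = np.empty((pre.size, post.size))
    cols = np.empty((mids.size, post.size))
    for i in range(mids.size):
        cols[i] = np.interp(post, mids, v[i])
    for j in range(post.size):
        out[:, j] = np.interp(pre, mids, cols[:, j])
    return out.squeeze()


def apply_class_adjustments(
    rules: pd.DataFrame, config: Mapping[str, Any]
) -> pd.DataFrame:
    """Apply the class-specific multiplicative connectivity adjustments.

    - L2/3 excitatory -> SOM cells of layers 4/5A/5B: probability x 1.5
    - L2/3 excitatory -> PV cells of layers 4/5A/5B: probability x 0.5
    - the opposite intralaminar pattern for L4/5A/5B IT -> PV (x 1.5) vs
      SOM (x 0.5), so PV receives stronger intralaminar input
    - rules targeting CT cells: strength x 0.62
    - L2/3 -> L4 excitatory strength rescaled to 1/4 of the L4 -> L2/3
      strength (the latter measured from the matching reciprocal rules)

    Probability adjustments act on s_con before decomposition (v_con is a
    property of the unitary connection, so scaling s scales p).  The
    operation is guarded against double application.
    """
    if rules.attrs.get("adjusted"):
        raise ValueError("class adjustments already applied (idempotency guard)")
    bands = config["wiring"]["interneuron_bands"]
    l23 = tuple(bands["L2/3"])
    l45 = tuple(bands["L4/5"])
    out = rules.copy()

    def mids(frame):
        return (frame["pre_lo"] + frame["pre_hi"]) / 2, (
            frame["post_lo"] + frame["post_hi"]
        ) / 2

    pre_mid, post_mid = mids(out)
    pre_l23 = (pre_mid >= l23[0]) & (pre_mid < l23[1])
    pre_l45 = (pre_mid >= l45[0]) & (pre_mid < l45[1])
    post_l45 = (post_mid >= l45[0]) & (post_mid < l45[1])

    sel = pre_l23 & post_l45 & (out["post_class"] == "SOM")
    out.loc[sel, "s_con"] *= 1.5
    sel = pre_l23 & post_l45 & (out["post_class"] == "PV")
    out.loc[sel, "s_con"] *= 0.5
    sel = pre_l45 & post_l45 & (out["post_class"] == "PV")
    out.loc[sel, "s_con"] *= 1.5
    sel = pre_l45 & post_l45 & (out["post_class"] == "SOM")
    out.loc[sel, "s_con"] *= 0.5

    out.loc[out["post_class"] == "CT", "s_con"] *= 0.62

    # L2/3 <-> L4 asymmetry on the excitatory-to-excitatory rules
    geom_layers = {s["name"]: (float(s["ncd_lo"]), float(s["ncd_hi"])) for s in config["layers"]}
    l23g, l4g = geom_layers.get("L2/3"), geom_layers.get("L4")
    if l23g and l4g:
        fwd = (
            (pre_mid >= l23g[0]) & (pre_mid < l23g[1])
            & (post_mid >= l4g[0]) & (post_mid < l4g[1])
            & (out["post_class"] == "IT")
        )
        rev = (
            (pre_mid >= l4g[0]) & (pre_mid < l4g[1])
            & (post_mid >= l23g[0]) & (post_mid < l23g[1])
            & (out["post_class"] == "IT")
        )
        if fwd.any() and rev.any():
            target = out.loc[rev, "s_con"].mean() / 4.0
            current = out.loc[fwd, "s_con"].mean()
            if current > 0:
                out.loc[fwd, "s_con"] *= target / current
    out.attrs["adjusted"] = True
    return out


def compute_delay(distance_um: float | np.ndarray, base_ms: float = 2.0,
                  speed_um_per_ms: float = 500.0) -> float | np.ndarray:
    """Connection delay: 2 ms base plus distance at 0.5 m/s (= 500 um/ms)."""
    d = np.asarray(distance_um, float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = base_ms + d / speed_um_per_ms
    return float(out) if np.isscalar(distance_um) else out


def _border_factors(
    cells: pd.DataFrame,
    radius_um: float,
    length_um: float,
    seed: int,
    mc_samples: int,
) -> np.ndarray:
    """Inverse of the exponential-kernel mass retained inside the cylinder.

    For each cell, sample lateral displacements from the 2-D kernel
    rho(r) ~ r exp(-r/lambda) (Gamma(2, lambda) radius, uniform angle) and
    count the fraction landing inside the cylinder cross-section.
    """
    rng = substream(seed, "border")
    n = len(cells)
    factors = np.ones(n)
    r = rng.gamma(2.0, length_um, size=(n, mc_samples))
    theta = rng.uniform(0, 2 * math.pi, size=(n, mc_samples))
    x = cells["x"].to_numpy()[:, None] + r * np.cos(theta)
    y = cells["y"].to_numpy()[:, None] + r * np.sin(theta)
    inside = (x * x + y * y) <= radius_um * radius_um
    frac = inside.mean(axis=1)
    frac = np.maximum(frac, 0.05)  # cap the boost for numerical safety
    return 1.0 / frac


def sample_connections(
    cells: pd.DataFrame,
    rules: pd.DataFrame,
    kernel: InhibKernel,
    config: Mapping[str, Any],
    seed: int,
) -> pd.DataFrame:
    """Draw the local connection set.

    Excitatory rules: for every ordered (pre, post) pair matched by a rule
    row, an independent Bernoulli draw with that row's p_con.  Rule rows
    must partition the (pre band, post class x band) space, so each pair is
    examined at most once (no duplicate connections, no autapses).

    Inhibitory connections: for each interneuron, Bernoulli draws over the
    cells of the same merged layer group with p0 * exp(-d / lambda), where
    d is the 3-D intersomatic distance; with border correction enabled,
    each *postsynaptic* cell's p0 is boosted by the inverse of the kernel
    mass retained inside the cylinder.

    Returns an edge table: pre_id, post_id, kind, v_con, p_used,
    distance_um, delay_ms.
    """
    rng = substream(seed, "wiring")
    clip = tuple(config["wiring"]["v_con_clip_mv"])
    base_ms = float(config["wiring"]["delay_base_ms"])
    speed = float(config["wiring"]["conduction_speed_um_per_ms"])
    radius = float(config["cylinder"]["diameter_um"]) / 2.0

    ids = cells["cell_id"].to_numpy()
    xyz = cells[["x", "y", "depth"]].to_numpy()
    ncd = cells["ncd"].to_numpy()
    cls = cells["cell_class"].to_numpy()

    out_pre: list[np.ndarray] = []
    out_post: list[np.ndarray] = []
    out_v: list[np.ndarray] = []
    out_p: list[np.ndarray] = []
    kinds: list[str] = []
    n_rows = 0

    # --- excitatory rules
    for rule in rules.itertuples():
        dec = decompose_strength(rule.s_con, rule.v_raw, clip)
        if dec.p_con <= 0:
            continue
        pre_mask = (
            (ncd >= rule.pre_lo) & (ncd < rule.pre_hi)
            & (np.char.startswith(cls.astype(str), rule.pre_class)
               if rule.pre_class not in ("E", "*")
               else np.isin(cls, ("IT", "PT", "CT")))
        )
        post_mask = (
            (ncd >= rule.post_lo) & (ncd < rule.post_hi) & (cls == rule.post_class)
        )
        pre_ids = ids[pre_mask]
        post_ids = ids[post_mask]
        if len(pre_ids) == 0 or len(post_ids) == 0:
            continue
        npair = len(pre_ids) * len(post_ids)
        draws = rng.random(npair) < dec.p_con
        hit = np.nonzero(draws)[0]
        pre_sel = pre_ids[hit // len(post_ids)]
        post_sel = post_ids[hit % len(post_ids)]
        keep = pre_sel != post_sel  # no autapses
        pre_sel, post_sel = pre_sel[keep], post_sel[keep]
        out_pre.append(pre_sel)
        out_post.append(post_sel)
        out_v.append(np.full(len(pre_sel), dec.v_con))
        out_p.append(np.full(len(pre_sel), dec.p_con))
        kinds.extend(["exc"] * len(pre_sel))
        n_rows += len(pre_sel)

    # --- inhibitory kernel
    merge_groups = config.get("merge_interneuron_layers", [])
    merged: dict[str, str] = {}
    for group in merge_groups:
        tag = "+".join(group)
        for member in group:
            merged[member] = tag
    layer_edges = [(s["name"], float(s["ncd_lo"]), float(s["ncd_hi"]))
                   for s in config["layers"]]

    def layer_group(ncd_val: float) -> str:
        for name, lo, hi in layer_edges:
            if lo <= ncd_val < hi or (hi == 1.0 and ncd_val == 1.0):
                return merged.get(name, name)
        return layer_edges[-1][0]

    groups = np.array([layer_group(v) for v in ncd])
    if kernel.border_correction:
        border = _border_factors(
            cells, radius, kernel.length_constant_um, seed, kernel.mc_samples
        )
    else:
        border = np.ones(len(cells))

    inh_v = config["wiring"].get("inh_v_con_mv", {"PV": 0.5, "SOM": 0.5})
    inh_idx = np.nonzero(np.isin(cls, ("PV", "SOM")))[0]
    for i in inh_idx:
        cand = np.nonzero((groups == groups[i]) & (ids != ids[i]))[0]
        if len(cand) == 0:
            continue
        d = np.sqrt(((xyz[cand] - xyz[i]) ** 2).sum(axis=1))
        p = kernel.base_probability * np.exp(-d / kernel.length_constant_um)
        p = np.minimum(p * border[cand], 1.0)
        hit = rng.random(len(cand)) < p
        sel = cand[hit]
        out_pre.append(np.full(len(sel), ids[i]))
        out_post.append(ids[sel])
        out_v.append(np.full(len(sel), float(inh_v.get(cls[i], 0.5))))
        out_p.append(p[hit])
        kinds.extend(["inh"] * len(sel))
        n_rows += len(sel)

    if n_rows == 0:
        return pd.DataFrame(
            columns=["pre_id", "post_id", "kind", "v_con", "p_used",
                     "distance_um", "delay_ms"]
        )
    pre_all = np.concatenate(out_pre)
    post_all = np.concatenate(out_post)
    id_to_row = pd.Series(np.arange(len(cells)), index=ids)
    d_all = np.sqrt(
        ((xyz[id_to_row[pre_all].to_numpy()] - xyz[id_to_row[post_all].to_numpy()]) ** 2).sum(axis=1)
    )
    table = pd.DataFrame(
        {
            "pre_id": pre_all,
            "post_id": post_all,
            "kind": pd.Categorical(kinds),
            "v_con": np.concatenate(out_v),
            "p_used": np.concatenate(out_p),
            "distance_um": d_all,
            "delay_ms": compute_delay(d_all, base_ms, speed),
        }
    )
    # one connection per ordered pair
    table = table.drop_duplicates(subset=["pre_id", "post_id"], keep="first")
    return table.reset_index(drop=True)


def rules_to_csv(rules: pd.DataFrame, path) -> None:
    rules[RULE_COLUMNS].to_csv(path, index=False)


def rules_from_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(RULE_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"rules file missing columns {sorted(missing)}")
    return frame
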