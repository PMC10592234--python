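"""Firing-rate statistics, estimated synaptic drive, and latent dynamics.

Estimated synaptic drive (ESD) between a presynaptic and a postsynaptic
population is

    S = (1 / N_post) * sum_i sum_j r_j * w_ij

where r_j is the rate of presynaptic cell j (Hz) and w_ij the summed
somatic-uPSP weight (mV) of all contacts from j onto postsynaptic cell i.
Because synaptic democracy makes every contact's somatic efficacy equal to
its mV weight regardless of dendritic position, rate x weight is a
meaningful drive estimate without simulating the synaptic currents.

Latent dynamics: binned population or single-cell rates are embedded in 3-D
with UMAP; cluster quality of behavioural-state labels is measured by the
silhouette coefficient, and the fidelity of the low-dimensional description
by the Pearson correlation between the original rates and their
reconstruction through the inverse mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .streams import substream

__all__ = [
    "cell_rates",
    "population_rates",
    "mean_rate_of",
    "esd",
    "esd_per_cell",
    "classify_enhanced_suppressed",
    "binned_rates",
    "LatentTrajectory",
    "latent_embedding",
    "esd_input_clusters",
    "compare_rates",
]


def cell_rates(
    spikes: np.ndarray,
    cell_ids: Sequence[int],
    epoch: tuple[float, float],
    zero_filter: bool = False,
) -> pd.Series:
    """Mean rate (Hz) per cell over the epoch (warm-up must be excluded by
    the caller's choice of epoch start).  With ``zero_filter`` the silent
    cells are dropped (the >0 Hz convention of some comparisons)."""
    t0, t1 = epoch
    if t1 <= t0:
        raise ValueError("epoch must have positive length")
    sel = spikes[(spikes[:, 1] >= t0) & (spikes[:, 1] < t1)]
    counts = pd.Series(0.0, index=pd.Index(cell_ids, name="cell_id"))
    if len(sel):
        got = pd.Series(sel[:, 0].astype(int)).value_counts()
        counts.loc[counts.index.intersection(got.index)] = got
    rates = counts / ((t1 - t0) / 1000.0)
    if zero_filter:
        rates = rates[rates > 0]
    return rates


def population_rates(
    network,
    result,
    epoch: tuple[float, float],
    zero_filter: bool = False,
    split_pt5b: bool = False,
) -> pd.DataFrame:
    """Per-population rate summary: mean, SD, median, IQR, n."""
    rows = []
    for pop in network.population_names(split_pt5b=split_pt5b):
        ids = network.cells_of(pop)
        r = cell_rates(result.spikes, ids, epoch, zero_filter=zero_filter)
        if len(r) == 0:
            rows.append({"pop": pop, "mean_hz": np.nan, "sd_hz": np.nan,
                         "median_hz": np.nan, "iqr_hz": np.nan, "n": 0})
            continue
        q1, q3 = np.percentile(r, [25, 75])
        rows.append({"pop": pop, "mean_hz": float(r.mean()), "sd_hz": float(r.std(ddof=0)),
                     "median_hz": float(r.median()), "iqr_hz": float(q3 - q1),
                     "n": int(len(r))})
    return pd.DataFrame(rows)


def mean_rate_of(network, result, pops: Sequence[str], epoch) -> float:
    ids = np.concatenate([network.cells_of(p) for p in pops])
    r = cell_rates(result.spikes, ids, epoch)
    return float(r.mean())


def _pop_of_cells(network, split_pt5b: bool = True) -> pd.Series:
    pop = network.cells.set_index("cell_id")["pop"].copy()
    if split_pt5b:
        for sub in ("PT5B_upper", "PT5B_lower"):
            pop.loc[network.cells_of(sub)] = sub
    return pop


def esd_per_cell(
    network,
    spikes: np.ndarray,
    epoch: tuple[float, float],
    longrange_rates: Mapping[str, np.ndarray] | None = None,
    split_pt5b: bool = True,
) -> pd.DataFrame:
    """Summed presynaptic rate x weight per (postsynaptic cell, source).

    Local sources are presynaptic populations; long-range sources are the
    seven regions (plus the generic inhibitory source) with the per-unit
    rates they were assigned.  Every synaptic contact contributes
    rate(pre) x weight_mv.
    """
    rates = cell_rates(spikes, network.cells["cell_id"], epoch)
    pop_of = _pop_of_cells(network, split_pt5b)

    pieces = []
    syn = network.synapses
    if syn is not None and len(syn):
        contrib = syn["weight_mv"].to_numpy() * rates.loc[syn["pre_id"]].to_numpy()
        frame = pd.DataFrame({
            "post_id": syn["post_id"].to_numpy(),
            "source": pop_of.loc[syn["pre_id"]].to_numpy(),
            "kind": syn["kind"].to_numpy(),
            "drive": contrib,
        })
        pieces.append(frame)
    lrs = network.longrange_synapses
    if lrs is not None and len(lrs) and longrange_rates is not None:
        unit_rates = np.empty(len(lrs))
        for region, sub in lrs.groupby("region"):
            r = longrange_rates.get(region)
            if r is None:
                unit_rates[sub.index] = 0.0
            else:
                unit_rates[sub.index] = np.asarray(r)[sub["unit"].to_numpy()]
        frame = pd.DataFrame({
            "post_id": lrs["post_id"].to_numpy(),
            "source": lrs["region"].to_numpy(),
            "kind": np.where(lrs["receptor"].str.startswith("GABA"), "inh", "exc"),
            "drive": lrs["weight_mv"].to_numpy() * unit_rates,
        })
        pieces.append(frame)
    if not pieces:
        return pd.DataFrame(columns=["post_id", "source", "kind", "drive"])
    all_contrib = pd.concat(pieces, ignore_index=True)
    return (
        all_contrib.groupby(["post_id", "source", "kind"], observed=True)["drive"]
        .sum()
        .reset_index()
    )


def esd(
    network,
    spikes: np.ndarray,
    epoch: tuple[float, float],
    longrange_rates: Mapping[str, np.ndarray] | None = None,
    split_pt5b: bool = True,
) -> pd.DataFrame:
    """Population-level ESD matrix (mV*Hz): sources x postsynaptic pops.

    Excitatory and inhibitory sources are reported as separate rows with
    positive magnitudes ('kind' column); totals should sum excitation and
    inhibition separately.  Long-range inhibition is included (its display
    is up to the caller).  Empty postsynaptic populations yield NaN.
    """
    per_cell = esd_per_cell(network, spikes, epoch, longrange_rates, split_pt5b)
    pop_of = _pop_of_cells(network, split_pt5b)
    rows = []
    pops = network.population_names(split_pt5b=split_pt5b)
    for post_pop in pops:
        ids = network.cells_of(post_pop)
        n_post = len(ids)
        sub = per_cell[per_cell["post_id"].isin(ids)]
        if n_post == 0:
            continue
        for (source, kind), grp in sub.groupby(["source", "kind"], observed=True):
            rows.append({
                "post_pop": post_pop, "source": str(source), "kind": str(kind),
                "esd_mv_hz": float(grp["drive"].sum()) / n_post,
                "sd": float(grp.groupby("post_id")["drive"].sum().reindex(ids, fill_value=0.0).std(ddof=0)),
            })
    return pd.DataFrame(rows, columns=["post_pop", "source", "kind", "esd_mv_hz", "sd"])


def classify_enhanced_suppressed(
    quiet_rates: pd.Series,
    move_rates: pd.Series,
    threshold_hz: float = 0.1,
) -> pd.Series:
    """Label each cell enhanced / suppressed / unchanged by the quiet-to-
    movement rate change (threshold in Hz)."""
    idx = quiet_rates.index.union(move_rates.index)
    q = quiet_rates.reindex(idx, fill_value=0.0)
    m = move_rates.reindex(idx, fill_value=0.0)
    diff = m - q
    out = pd.Series("unchanged", index=idx)
    out[diff > threshold_hz] = "enhanced"
    out[diff < -threshold_hz] = "suppressed"
    return out


def binned_rates(
    spikes: np.ndarray,
    groups: Mapping[Any, np.ndarray],
    bin_ms: float,
    t_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean firing rate (Hz) per time bin for each group of cells.

    Returns (bin centers ms, rates [n_bins, n_groups]).
    """
    t0, t1 = t_range
    edges = np.arange(t0, t1 + bin_ms / 2, bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.zeros((len(centers), len(groups)))
    for g, (name, ids) in enumerate(groups.items()):
        ids = np.asarray(ids)
        if len(ids) == 0:
            continue
        sel = spikes[np.isin(spikes[:, 0].astype(int), ids)]
        counts, _ = np.histogram(sel[:, 1], bins=edges)
        out[:, g] = counts / len(ids) / (bin_ms / 1000.0)
    return centers, out


@dataclass
class LatentTrajectory:
    """3-D latent trajectory of binned network activity."""

    embedding: np.ndarray  # [n_bins, 3]
    smoothed: np.ndarray  # spline-smoothed for display
    labels: np.ndarray
    bin_ms: float
    silhouette: float
    reconstruction_r: float
    params: dict[str, Any] = field(default_factory=dict)


def latent_embedding(
    rates: np.ndarray,
    labels: Sequence[Any],
    seed: int,
    bin_ms: float = 25.0,
    n_neighbors: int = 100,
    min_dist: float = 0.95,
    n_components: int = 3,
) -> LatentTrajectory:
    """UMAP embedding of binned rates with silhouette and reconstruction.

    ``rates`` is [n_bins, n_features] (cells or populations); ``labels``
    assigns a behavioural state to each bin.  The reconstruction r is the
    Pearson correlation between the original rate matrix and its inverse
    transform from the embedding.  Trajectories are smoothed with a cubic
    smoothing spline per dimension for display.
    """
    import umap
    from scipy.interpolate import make_smoothing_spline
    from sklearn.metrics import silhouette_score

    x = np.asarray(rates, float)
    labels = np.asarray(labels)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 time bins")
    nn = min(n_neighbors, x.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=n_components, n_neighbors=nn, min_dist=min_dist,
        random_state=int(seed) % (2**31),
    )
    emb = np.asarray(reducer.fit_transform(x), float)

    sil = float("nan")
    if len(np.unique(labels)) >= 2:
        sil = float(silhouette_score(emb, labels))

    try:
        recon = reducer.inverse_transform(emb)
        r = float(np.corrcoef(x.ravel(), np.asarray(recon, float).ravel())[0, 1])
    except Exception:  # pragma: no cover - inverse not always available
        r = float("nan")

    t = np.arange(x.shape[0], dtype=float)
    smoothed = np.empty_like(emb)
    for d in range(emb.shape[1]):
        try:
            spl = make_smoothing_spline(t, emb[:, d], lam=1e-3)
            smoothed[:, d] = spl(t)
        except Exception:  # pragma: no cover - degenerate input
            smoothed[:, d] = emb[:, d]

    return LatentTrajectory(
        embedding=emb, smoothed=smoothed, labels=labels, bin_ms=bin_ms,
        silhouette=sil, reconstruction_r=r,
        params={"n_neighbors": nn, "min_dist": min_dist, "n_components": n_components},
    )


def esd_input_clusters(
    per_cell_esd: pd.DataFrame,
    seed: int,
    overlays: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster PT5B cells by their presynaptic-population ESD vectors.

    ``per_cell_esd`` is a cells x sources table of drives.  Returns a table
    with the 2-D UMAP coordinates, the k=2 K-means labels, and any overlay
    columns (NCD, firing rate) joined on the cell index.
    """
    import umap
    from sklearn.cluster import KMeans

    x = per_cell_esd.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    nn = min(15, x.shape[0] - 1)
    emb = umap.UMAP(n_components=2, n_neighbors=nn, min_dist=0.1,
                    random_state=int(seed) % (2**31)).fit_transform(x)
    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(emb)
    out = pd.DataFrame(
        {"u1": emb[:, 0], "u2": emb[:, 1], "cluster": labels},
        index=per_cell_esd.index,
    )
    if overlays is not None:
        out = out.join(overlays)
    return out


def compare_rates(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_comparisons: int = 1,
    zero_filter: bool = False,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with Bonferroni correction.

    Returns (statistic, corrected p).  With ``zero_filter`` only rates
    above 0 Hz enter the comparison.  Fully tied degenerate samples fall
    back to the exact Mann-Whitney method.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if zero_filter:
        a, b = a[a > 0], b[b > 0]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ranksums(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    return stat, min(1.0, p * n_comparisons)
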