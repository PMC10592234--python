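"""Local field potentials: line-source forward model and band-power stats.

The extracellular potential at an electrode is the sum over all compartments
of the membrane current weighted by the line-source transfer coefficient of
the compartment's segment, assuming a homogeneous, frequency-independent
medium (conductivity sigma = 0.3 mS/mm).  Per-population LFPs use the same
transfer coefficients restricted to one population's compartments, so the
decomposition is exactly additive.

Spectral statistics follow the experimental pipeline: the signal is cut
into 4-s segments; each segment's power spectral density is estimated with
the complex Morlet wavelet transform (omega = 6), min-max normalized to
[0, 1] across the frequency grid, and averaged within the five canonical
bands: delta (0-4 Hz), theta (4-8), alpha (8-12), beta (12-30) and gamma
(30-80 Hz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .streams import substream

__all__ = [
    "Electrode",
    "BAND_EDGES",
    "line_source_coefficients",
    "line_source_lfp",
    "population_lfp",
    "morlet_psd",
    "band_power",
    "paired_delta",
    "lfp_outlier_clusters",
]

BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 80.0),
}
BAND_NAMES = tuple(BAND_EDGES)


@dataclass(frozen=True)
class Electrode:
    """Recording site inside the cylinder; depth in um below the pia."""

    x: float = 0.0
    y: float = 0.0
    depth: float = 800.0
    sigma_ms_per_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma_ms_per_mm <= 0:
            raise ValueError("conductivity must be positive")


def line_source_coefficients(
    comp_table: pd.DataFrame, electrode: Electrode, min_r_um: float = 1.0
) -> np.ndarray:
    """Transfer coefficient (uV per nA) for each compartment segment.

    Uses the stable inverse-hyperbolic form of the line-source integral,
    phi = I / (4 pi sigma L) * [asinh(b/r) - asinh(a/r)], where r is the
    perpendicular distance from the electrode to the segment's line and
    a, b the signed longitudinal distances to its two ends.  In the limit
    L -> 0 this reduces to the point source 1 / (4 pi sigma d).  An
    electrode closer than ``min_r_um`` to a segment is clamped to that
    distance (with a warning), which regularizes the divergence.
    """
    p0 = comp_table[["x0", "y0", "z0"]].to_numpy(float)
    p1 = comp_table[["x1", "y1", "z1"]].to_numpy(float)
    e = np.array([electrode.x, electrode.y, electrode.depth], float)

    seg = p1 - p0
    seg_len = np.linalg.norm(seg, axis=1)
    rel = e - p0
    # longitudinal coordinate of the electrode projection along the segment
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(seg_len[:, None] > 0, seg / np.where(seg_len[:, None] > 0, seg_len[:, None], 1.0), 0.0)
    s0 = (rel * unit).sum(axis=1)
    r_vec = rel - s0[:, None] * unit
    r = np.linalg.norm(r_vec, axis=1)
    clamped = r < min_r_um
    point_like = seg_len < 1e-6
    d_point = np.linalg.norm(e - 0.5 * (p0 + p1), axis=1)
    if np.any(clamped & ~point_like) or np.any(point_like & (d_point < min_r_um)):
        warnings.warn("electrode within min distance of a segment; clamping")
    r = np.maximum(r, min_r_um)
    d_point = np.maximum(d_point, min_r_um)

    a = -s0
    b = seg_len - s0
    sigma = electrode.sigma_ms_per_mm  # mS/mm == S/m
    scale = 1000.0 / (4.0 * math.pi * sigma)  # -> uV for nA and um
    with np.errstate(invalid="ignore", divide="ignore"):
        line = scale / seg_len * (np.arcsinh(b / r) - np.arcsinh(a / r))
    point = scale / d_point
    return np.where(point_like, point, line)


def line_source_lfp(
    currents: np.ndarray,
    comp_table: pd.DataFrame,
    electrode: Electrode,
    comp_mask: np.ndarray | None = None,
) -> np.ndarray:
    """LFP trace (uV): membrane currents (nA, [nt, ncomp]) through the
    line-source transfer coefficients, optionally restricted by a mask."""
    coeff = line_source_coefficients(comp_table, electrode)
    if comp_mask is not None:
        coeff = np.where(comp_mask, coeff, 0.0)
    return currents.astype(float) @ coeff


def population_lfp(
    currents: np.ndarray,
    comp_table: pd.DataFrame,
    electrode: Electrode,
    population: str | Sequence[str],
    cells_table: pd.DataFrame | None = None,
    network=None,
) -> np.ndarray:
    """LFP restricted to the transmembrane currents of one population.

    ``PT5B_upper``/``PT5B_lower`` are resolved by NCD through ``network``.
    Summing the per-population traces over a partition of the populations
    reproduces the total LFP exactly (linearity).
    """
    pops = [population] if isinstance(population, str) else list(population)
    mask = np.zeros(len(comp_table), bool)
    for p in pops:
        if p in ("PT5B_upper", "PT5B_lower") and network is not None:
            ids = set(network.cells_of(p))
            mask |= comp_table["cell_id"].isin(ids).to_numpy()
        else:
            mask |= (comp_table["pop"] == p).to_numpy()
    return line_source_lfp(currents, comp_table, electrode, comp_mask=mask)


def morlet_psd(
    trace: np.ndarray,
    fs_hz: float,
    freqs_hz: np.ndarray | None = None,
    omega: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density via the complex Morlet wavelet transform.

    Returns (freqs, mean |W|^2 over time).  ``omega`` is the Morlet
    time-frequency tradeoff; the pywt parameterisation cmorB-C uses
    B = 2 and C = omega / (2 pi).
    """
    if freqs_hz is None:
        freqs_hz = np.logspace(0.0, 2.0, 60)
    fc = omega / (2.0 * math.pi)
    wavelet = f"cmor2.0-{fc:.6f}"
    dt = 1.0 / fs_hz
    scales = fc / (np.asarray(freqs_hz) * dt)
    coeffs, _ = pywt.cwt(np.asarray(trace, float), scales, wavelet, sampling_period=dt)
    psd = (np.abs(coeffs) ** 2).mean(axis=1)
    return np.asarray(freqs_hz, float), psd


def band_power(
    trace: np.ndarray,
    fs_hz: float,
    segment_len_s: float = 4.0,
    freq_grid: tuple[float, float, int] = (1.0, 100.0, 60),
    omega: float = 6.0,
    normalization: str = "minmax",
) -> pd.DataFrame:
    """Per-segment normalized band power vectors.

    The trace is cut into consecutive ``segment_len_s`` segments (a final
    shorter remainder is dropped and counted in ``attrs['dropped']``).
    For each segment the Morlet PSD is normalized to [0, 1] ("minmax",
    the default) or to unit total power ("total"), then averaged within
    each canonical band.
    """
    if normalization not in ("minmax", "total"):
        raise ValueError("normalization must be 'minmax' or 'total'")
    n_seg_len = int(round(segment_len_s * fs_hz))
    if len(trace) < n_seg_len:
        raise ValueError("trace shorter than one segment")
    freqs = np.logspace(math.log10(freq_grid[0]), math.log10(freq_grid[1]), freq_grid[2])
    n_seg = len(trace) // n_seg_len
    dropped = 1 if len(trace) % n_seg_len else 0
    rows = []
    for i in range(n_seg):
        seg = np.asarray(trace[i * n_seg_len : (i + 1) * n_seg_len], float)
        # remove the per-segment linear trend: a 4-s window holds few
        # cycles of the lowest analysed frequencies, so residual drift
        # would otherwise masquerade as a large delta peak
        seg = signal.detrend(seg)
        _, psd = morlet_psd(seg, fs_hz, freqs, omega)
        if normalization == "minmax":
            lo, hi = psd.min(), psd.max()
            norm = (psd - lo) / (hi - lo) if hi > lo else np.zeros_like(psd)
        else:
            norm = psd / psd.sum() if psd.sum() > 0 else psd
        row = {"segment": i}
        for name, (f_lo, f_hi) in BAND_EDGES.items():
            m = (freqs >= f_lo) & (freqs < f_hi)
            row[name] = float(norm[m].mean()) if m.any() else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    out.attrs["normalization"] = normalization
    return out


def paired_delta(
    band_vectors: pd.DataFrame,
    states: Sequence[str],
    recordings: Sequence[Any],
) -> pd.DataFrame:
    """Movement-minus-quiet band differences for consecutive segment pairs.

    A pair is a quiet segment immediately followed by a movement segment
    within the same recording.  Returns one row of band deltas per pair.
    """
    states = np.asarray(states)
    recordings = np.asarray(recordings)
    bands = [b for b in BAND_NAMES if b in band_vectors.columns]
    rows = []
    for i in range(len(band_vectors) - 1):
        if (
            recordings[i] == recordings[i + 1]
            and states[i] == "quiet"
            and states[i + 1] == "movement"
        ):
            delta = band_vectors.iloc[i + 1][bands].to_numpy(float) - band_vectors.iloc[i][bands].to_numpy(float)
            rows.append({"pair": len(rows), "recording": recordings[i],
                         **dict(zip(bands, delta))})
    return pd.DataFrame(rows, columns=["pair", "recording", *bands])


def lfp_outlier_clusters(
    band_vectors: pd.DataFrame,
    seed: int,
    n_clusters: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Outlier removal: 2-D embedding + K-means (k=2), keep the big cluster.

    Returns (cluster labels, boolean mask of the larger cluster).  If all
    vectors are identical the clustering is degenerate: everything is
    assigned to a single retained cluster (with a warning).
    """
    from sklearn.cluster import KMeans

    bands = [b for b in BAND_NAMES if b in band_vectors.columns]
    x = band_vectors[bands].to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least 2 segments per state")
    if np.allclose(x, x[0]):
        warnings.warn("all band vectors identical; single-cluster fallback")
        return np.zeros(len(x), int), np.ones(len(x), bool)
    emb = _umap_2d(x, seed)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(emb)
    counts = np.bincount(labels, minlength=n_clusters)
    big = int(np.argmax(counts))
    return labels, labels == big


def _umap_2d(x: np.ndarray, seed: int) -> np.ndarray:
    import umap

    n_neighbors = min(15, max(2, len(x) - 1))
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=0.1,
        random_state=int(seed) % (2**31),
    )
    return reducer.fit_transform(x)
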