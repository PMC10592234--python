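"""Synapse placement, weight normalization and receptor kinetics.

Weights are expressed as somatic unitary-EPSP equivalents (mV).  The
*synaptic democracy* rule converts them to conductances: for each template
compartment, the conductance needed to evoke a 0.5 mV somatic EPSP is found
by bisection on an isolated single-EPSP protocol; the per-compartment scale
factor (relative to the soma) compensates dendritic attenuation, capped at
4.0 so distal tuft synapses cannot overexcite the network.

Contacts are distributed over the dendritic tree either uniformly by
dendritic length or following a projection-specific radial density profile
(sCRACM-style: map amplitude divided by dendritic length, averaged across
the horizontal axis).  PV outputs onto excitatory cells are perisomatic
(within 50 um of the soma); SOM outputs and all inputs onto interneurons
target apical dendrites.  Excitatory synapses carry colocalized AMPA+NMDA
(50/50 by weight, NMDA under a voltage-dependent Mg2+ block); SOM->E
synapses carry slow GABA_A and GABA_B in a 90/10 proportion, SOM->I slow
GABA_A only, PV fast GABA_A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import CellTemplate
from .streams import substream

__all__ = [
    "DemocracyMap",
    "RadialDensityProfile",
    "compute_democracy_map",
    "profile_from_map",
    "place_synapses",
    "nmda_mg_factor",
    "epsp_peak",
]


@dataclass(frozen=True)
class DemocracyMap:
    """Per-compartment synaptic scale factors for one template."""

    template_name: str
    factors: np.ndarray  # dimensionless, in (0, max_factor]
    g05_soma_us: float  # conductance for a 0.5 mV somatic EPSP at the soma
    raw_factors: np.ndarray  # before capping

    def weight_to_g(self, weight_mv: float, comp: int) -> float:
        """Convert a somatic-EPSP-equivalent weight (mV) to a conductance."""
        return weight_mv / 0.5 * self.g05_soma_us * self.factors[comp]


@dataclass(frozen=True)
class RadialDensityProfile:
    """Normalized synaptic density along the radial (depth) axis."""

    projection: tuple[str, str]  # (pre label, post class)
    weights: np.ndarray  # per radial bin, sums to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("profile weights must be >= 0 with positive sum")
        object.__setattr__(self, "weights", w / w.sum())


def nmda_mg_factor(v_mv: float | np.ndarray, mg_mm: float = 1.0):
    """Voltage-dependent Mg2+ relief of the NMDA conductance.

    1 / (1 + 0.28 * Mg * exp(-0.062 V)); Mg in mM, V in mV.  Strictly
    increasing in V for Mg > 0 and equal to 1 when Mg = 0.
    """
    if mg_mm < 0:
        raise ValueError("Mg concentration must be >= 0")
    return 1.0 / (1.0 + 0.28 * mg_mm * np.exp(-0.062 * np.asarray(v_mv, float)))


def epsp_peak(
    template: CellTemplate,
    comp: int,
    g_us: float,
    settle_ms: float = 200.0,
    window_ms: float = 50.0,
    dt_ms: float = 0.025,
    receptor: str = "AMPA",
) -> float:
    """Somatic EPSP peak (mV) from one isolated synaptic event on ``comp``."""
    from .engine import simulate_single_cell

    res = simulate_single_cell(
        template,
        duration_ms=settle_ms + window_ms,
        dt_ms=dt_ms,
        events=[(settle_ms, comp, receptor, g_us)],
        mg_mm=0.0,
    )
    v = res.voltages[:, 0]
    i0 = int(settle_ms / dt_ms) - 1
    base = v[i0]
    return float(v[i0:].max() - base)


def compute_democracy_map(
    template: CellTemplate,
    target_mv: float = 0.5,
    max_factor: float = 4.0,
    tol: float = 0.01,
    settle_ms: float = 200.0,
    window_ms: float = 50.0,
) -> DemocracyMap:
    """Bisect per-compartment conductances for a ``target_mv`` somatic EPSP.

    The scale factor of each compartment is its required conductance
    normalized to the somatic one, capped at ``max_factor``.  Raises if the
    bisection cannot bracket the target on some compartment.
    """
    n = template.n_comp
    g_needed = np.empty(n)
    for comp in range(n):
        lo, hi = 0.0, 1e-4
        peak = epsp_peak(template, comp, hi, settle_ms, window_ms)
        n_doublings = 0
        while peak < target_mv:
            lo = hi
            hi *= 2.0
            n_doublings += 1
            if n_doublings > 30:
                raise RuntimeError(
                    f"democracy bisection failed to bracket on compartment "
                    f"{template.compartments[comp].name} of {template.template_name}"
                )
            peak = epsp_peak(template, comp, hi, settle_ms, window_ms)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            peak = epsp_peak(template, comp, mid, settle_ms, window_ms)
            if abs(peak - target_mv) <= tol * target_mv:
                break
            if peak < target_mv:
                lo = mid
            else:
                hi = mid
        else:
            raise RuntimeError(
                f"democracy bisection did not converge on compartment "
                f"{template.compartments[comp].name} of {template.template_name}"
            )
        g_needed[comp] = mid

    soma = 0
    raw = g_needed / g_needed[soma]
    factors = np.minimum(raw, max_factor)
    return DemocracyMap(
        template_name=template.template_name,
        factors=factors,
        g05_soma_us=float(g_needed[soma]),
        raw_factors=raw,
    )


def profile_from_map(
    map_amplitudes: np.ndarray, dendritic_length: np.ndarray,
    projection: tuple[str, str] = ("", ""),
) -> RadialDensityProfile:
    """Radial density from an sCRACM-style map.

    Elementwise amplitude / dendritic length, averaged across the horizontal
    axis (columns) within each radial row, normalized to sum 1.
    """
    amp = np.asarray(map_amplitudes, float)
    length = np.asarray(dendritic_length, float)
    if amp.shape != length.shape:
        raise ValueError("amplitude and length grids must have the same shape")
    if np.any((amp > 0) & (length <= 0)):
        raise ValueError("positive amplitude at a grid point with zero dendritic length")
    ratio = np.where(length > 0, amp / np.where(length > 0, length, 1.0), 0.0)
    profile = ratio.mean(axis=1)
    return RadialDensityProfile(projection=projection, weights=profile)


# --- contact placement -----------------------------------------------------


def _dendritic_comps(template: CellTemplate) -> np.ndarray:
    return np.array(
        [c.comp_id for c in template.compartments if c.role in
         ("basal", "apical_trunk", "apical_tuft")],
        int,
    )


def _apical_comps(template: CellTemplate) -> np.ndarray:
    return np.array(template.apical_comp_ids(), int)


def _perisomatic_comps(template: CellTemplate, radius_um: float) -> np.ndarray:
    out = [c.comp_id for c in template.compartments
           if template.path_distance(c.comp_id) <= radius_um and c.role != "axon"]
    return np.array(out if out else [0], int)


def _comp_for_radial_position(template: CellTemplate, pos: np.ndarray) -> np.ndarray:
    """Map normalized radial positions (0 = soma, 1 = pia-most tip) onto
    apical compartments by normalized path distance."""
    apical = _apical_comps(template)
    extent = template.apical_extent()
    if extent <= 0 or len(apical) == 0:
        return np.zeros(len(pos), int)
    mids = np.array([template.path_distance(c) / extent for c in apical])
    order = np.argsort(mids)
    idx = np.searchsorted(mids[order], pos, side="left")
    idx = np.clip(idx, 0, len(apical) - 1)
    return apical[order][idx]


def place_synapses(
    connections: pd.DataFrame,
    cell_template: Mapping[int, str],
    templates: Mapping[str, CellTemplate],
    democracy_maps: Mapping[str, DemocracyMap],
    config: Mapping[str, Any],
    seed: int,
    profiles: Mapping[tuple[str, str], RadialDensityProfile] | None = None,
    pre_class_of: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Expand the connection list into per-contact synapse rows.

    Each connection becomes n_syn contacts (5 onto detailed templates, 1
    otherwise); each contact is split into its receptor components.  The
    per-contact mV-equivalent weight is v_con / n_syn; its conductance is
    that weight through the postsynaptic template's democracy map at the
    contact compartment.
    """
    rng = substream(seed, "placement")
    syn_cfg = config["synapses"]
    n_detail = int(config["wiring"].get("n_syn_detailed", 5))
    peri_um = float(syn_cfg.get("pv_perisomatic_um", 50.0))
    gabab_frac = float(syn_cfg.get("som_gabab_fraction", 0.10))
    profiles = profiles or {}

    rows: list[tuple] = []
    for conn in connections.itertuples():
        post_tname = cell_template[conn.post_id]
        tpl = templates[post_tname]
        dmap = democracy_maps[post_tname]
        n_syn = n_detail if tpl.detailed else 1
        w_mv = conn.v_con / n_syn
        pre_cls = pre_class_of[conn.pre_id] if pre_class_of else (
            "PV" if conn.kind == "inh" else "IT"
        )
        post_is_exc = tpl.is_excitatory

        if conn.kind == "inh" and pre_cls == "PV" and post_is_exc:
            pool = _perisomatic_comps(tpl, peri_um)
            comps = pool[rng.integers(0, len(pool), n_syn)]
        elif conn.kind == "inh" or not post_is_exc:
            pool = _apical_comps(tpl)
            if len(pool) == 0:
                pool = _dendritic_comps(tpl)
            comps = pool[rng.integers(0, len(pool), n_syn)]
        else:
            key = (pre_cls, tpl.class_name)
            prof = profiles.get(key)
            if prof is not None:
                nb = len(prof.weights)
                bins = rng.choice(nb, size=n_syn, p=prof.weights)
                pos = (bins + rng.random(n_syn)) / nb
                comps = _comp_for_radial_position(tpl, pos)
            else:
                # uniform by dendritic length
                pool = _dendritic_comps(tpl)
                lens = np.array([tpl.compartments[c].length for c in pool])
                comps = pool[rng.choice(len(pool), size=n_syn, p=lens / lens.sum())]

        pos_along = rng.random(n_syn)
        for j in range(n_syn):
            comp = int(comps[j])
            g_full = dmap.weight_to_g(w_mv, comp)
            if conn.kind == "exc":
                recs = (("AMPA", 0.5), ("NMDA", 0.5))
            elif pre_cls == "SOM" and post_is_exc:
                recs = (("GABAA_slow", 1.0 - gabab_frac), ("GABAB", gabab_frac))
            elif pre_cls == "SOM":
                recs = (("GABAA_slow", 1.0),)
            else:
                recs = (("GABAA_fast", 1.0),)
            for rec, frac in recs:
                rows.append(
                    (conn.pre_id, conn.post_id, comp, pos_along[j], rec,
                     w_mv * frac, g_full * frac, conn.delay_ms, conn.kind)
                )

    return pd.DataFrame(
        rows,
        columns=["pre_id", "post_id", "comp", "pos", "receptor",
                 "weight_mv", "g_us", "delay_ms", "kind"],
    )
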