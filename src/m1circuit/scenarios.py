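"""Condition presets, fixture network construction, and batch running.

The experimental conditions are condition x behavioural-state presets:

=======================  ===========  =======  ====================
preset                   ih_fraction  k_scale  long-range drive
=======================  ===========  =======  ====================
quiet                    0.75         1.0      all regions 0-5 Hz
movement                 0.25         1.0      VL (MTh) 0-10 Hz
mth_inact_quiet          0.75         1.0      VL removed
mth_inact_movement       0.25         1.0      VL removed
mth_inact_movement_modified   0.25    1.0      VL removed, cM1/M2 halved
nar_block_quiet          1.0          1.0      all regions 0-5 Hz
nar_block_movement       1.0          1.0      VL 0-10 Hz
nar_block_movement_modified   1.0     1.5      VL 0-10 Hz
=======================  ===========  =======  ====================

ih_fraction is the PT-cell HCN conductance fraction (the proxy for
noradrenergic tone: low NA = high I_h); k_scale multiplies the excitatory
voltage-gated K+ conductances (the modified NA-R-block manipulation).

:func:`build_fixture_network` instantiates the whole pipeline (geometry ->
cells -> wiring -> synapses -> drive) at a configurable density scale.  The
connection-strength matrices packaged here are a synthetic fixture that
follows the qualitative wiring of the mouse M1 microcircuit (strong
L2/3 -> upper PT5B, unidirectional IT -> PT, L4 -> L2/3 four times stronger
than its reciprocal, CT targets at 62%).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import make_template, adapt_apical_length
from .config import ConfigurationError, default_config
from .drive import REGIONS, assign_rates, build_longrange_synapses
from .engine import SimulationConfig, SimulationResult, run_simulation
from .geometry import build_geometry, layers_from_config
from .network import NetworkModel
from .streams import substream
from .synapses import (
    RadialDensityProfile,
    compute_democracy_map,
    place_synapses,
)
from .wiring import InhibKernel, apply_class_adjustments, interp_vcon, sample_connections

__all__ = [
    "ScenarioPreset",
    "GridSpec",
    "scenario_preset",
    "scenario_rates",
    "fixture_strength_rules",
    "fixture_profiles",
    "build_fixture_network",
    "run_scenario",
    "run_grid",
    "generate_synthetic_observables",
    "readiness_check",
]


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    ih_fraction: float
    k_scale: float
    increased_regions: tuple[str, ...] = ()
    removed_regions: tuple[str, ...] = ()
    rate_scale: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GridSpec:
    """MTh x NA exploration grid (5 x 5 by default).

    ``mth_levels`` are the upper bounds of the VL rate range in Hz (None =
    region removed); ``na_levels`` are PT ih_fraction values (1.0 = no NA,
    0.25 = high NA).
    """

    mth_levels: tuple[float | None, ...] = (None, 2.5, 5.0, 7.5, 10.0)
    na_levels: tuple[float, ...] = (1.0, 0.8125, 0.625, 0.4375, 0.25)
    input_seeds: tuple[int, ...] = (0,)


def scenario_preset(config: Mapping[str, Any], name: str) -> dict[str, Any]:
    presets = config["scenarios"]
    if name not in presets:
        raise ConfigurationError(f"unknown scenario {name!r}; known: {sorted(presets)}")
    p = dict(presets[name])
    p.setdefault("rate_scale", {})
    return p


def scenario_rates(
    network: NetworkModel, preset: Mapping[str, Any], input_seed: int
) -> dict[str, np.ndarray]:
    """Per-region per-unit rates for one scenario preset and input seed."""
    lr = network.config["longrange"]
    n_units = int(lr["n_units"])
    spont = tuple(lr["spontaneous_rate_hz"])
    by_region = lr.get("spontaneous_rate_by_region", {})
    incr = tuple(lr["increased_rate_hz"])
    removed = set(preset.get("removed_regions", ()))
    increased = set(preset.get("increased_regions", ()))
    scale = preset.get("rate_scale", {})
    rates: dict[str, np.ndarray] = {}
    for region in REGIONS:
        if region in removed:
            continue
        if region in increased:
            rng = incr
        else:
            rng = tuple(by_region.get(region, spont))
        r = assign_rates(region, rng, n_units, input_seed)
        rates[region] = r * float(scale.get(region, 1.0))
    # generic long-range inhibitory source always at spontaneous level
    rates["INH"] = assign_rates("INH", spont, n_units, input_seed)
    return rates


# ---------------------------------------------------------------------------
# fixture connectivity data (synthetic stand-in for the deposited matrices)


_BANDS = {
    "L2/3": (0.10, 0.29),
    "L4": (0.29, 0.37),
    "L5A": (0.37, 0.47),
    "L5Bu": (0.47, 0.635),
    "L5Bl": (0.635, 0.80),
    "L6": (0.80, 1.00),
}
_IBANDS = {"L2/3": (0.12, 0.31), "L4/5": (0.31, 0.77), "L6": (0.77, 1.00)}

# s_con (mV) from presynaptic excitatory band to postsynaptic (class, band).
# Key qualitative features: strong L2/3 -> upper L5B PT, unidirectional
# IT -> PT (no PT -> IT/CT rows), recurrent intralaminar excitation,
# deep L6 loop, L4 -> L2/3 feedforward.
_EE_SCON: dict[tuple[str, str, str], float] = {
    # (pre band, post class, post band): s_con mV
    ("L2/3", "IT", "L2/3"): 0.30, ("L2/3", "IT", "L4"): 0.20,
    ("L2/3", "IT", "L5A"): 0.55, ("L2/3", "IT", "L5Bu"): 0.30,
    ("L2/3", "IT", "L5Bl"): 0.25, ("L2/3", "IT", "L6"): 0.08,
    ("L2/3", "PT", "L5Bu"): 0.80, ("L2/3", "PT", "L5Bl"): 0.25,
    ("L2/3", "CT", "L6"): 0.10,
    ("L4", "IT", "L2/3"): 0.80, ("L4", "IT", "L4"): 0.40,
    ("L4", "IT", "L5A"): 0.30, ("L4", "IT", "L5Bu"): 0.20,
    ("L4", "IT", "L5Bl"): 0.15, ("L4", "IT", "L6"): 0.05,
    ("L4", "PT", "L5Bu"): 0.30, ("L4", "PT", "L5Bl"): 0.20,
    ("L4", "CT", "L6"): 0.08,
    ("L5A", "IT", "L2/3"): 0.15, ("L5A", "IT", "L4"): 0.10,
    ("L5A", "IT", "L5A"): 0.40, ("L5A", "IT", "L5Bu"): 0.30,
    ("L5A", "IT", "L5Bl"): 0.25, ("L5A", "IT", "L6"): 0.10,
    ("L5A", "PT", "L5Bu"): 0.40, ("L5A", "PT", "L5Bl"): 0.30,
    ("L5A", "CT", "L6"): 0.10,
    ("L5Bu", "IT", "L2/3"): 0.05, ("L5Bu", "IT", "L5A"): 0.20,
    ("L5Bu", "IT", "L5Bu"): 0.40, ("L5Bu", "IT", "L5Bl"): 0.30,
    ("L5Bu", "IT", "L6"): 0.15,
    ("L5Bu", "PT", "L5Bu"): 0.45, ("L5Bu", "PT", "L5Bl"): 0.30,
    ("L5Bu", "CT", "L6"): 0.10,
    ("L5Bl", "IT", "L5A"): 0.15, ("L5Bl", "IT", "L5Bu"): 0.30,
    ("L5Bl", "IT", "L5Bl"): 0.40, ("L5Bl", "IT", "L6"): 0.20,
    ("L5Bl", "PT", "L5Bu"): 0.30, ("L5Bl", "PT", "L5Bl"): 0.45,
    ("L5Bl", "CT", "L6"): 0.12,
    ("L6", "IT", "L5Bu"): 0.10, ("L6", "IT", "L5Bl"): 0.15,
    ("L6", "IT", "L6"): 0.30, ("L6", "CT", "L6"): 0.30,
}

# PT outputs: recurrent PT and excitation of interneurons only (the IT -> PT
# projection is unidirectional).
_PT_SCON: dict[tuple[str, str, str], float] = {
    ("L5Bu", "PT", "L5Bu"): 0.30, ("L5Bu", "PT", "L5Bl"): 0.20,
    ("L5Bl", "PT", "L5Bu"): 0.20, ("L5Bl", "PT", "L5Bl"): 0.30,
}

# excitatory drive of interneurons: intralaminar-dominant base values; the
# L2/3->SOM(+50%)/PV(-50%) and intralaminar-opposite adjustments are applied
# by apply_class_adjustments afterwards.
_EI_SCON: dict[tuple[str, str, str], float] = {
    ("L2/3", "PV", "L2/3"): 0.45, ("L2/3", "SOM", "L2/3"): 0.30,
    ("L2/3", "PV", "L4/5"): 0.30, ("L2/3", "SOM", "L4/5"): 0.30,
    ("L4", "PV", "L2/3"): 0.20, ("L4", "SOM", "L2/3"): 0.15,
    ("L4", "PV", "L4/5"): 0.45, ("L4", "SOM", "L4/5"): 0.30,
    ("L5A", "PV", "L4/5"): 0.45, ("L5A", "SOM", "L4/5"): 0.30,
    ("L5Bu", "PV", "L4/5"): 0.45, ("L5Bu", "SOM", "L4/5"): 0.30,
    ("L5Bl", "PV", "L4/5"): 0.45, ("L5Bl", "SOM", "L4/5"): 0.30,
    ("L6", "PV", "L6"): 0.45, ("L6", "SOM", "L6"): 0.30,
    ("L5Bl", "PV", "L6"): 0.10, ("L6", "PV", "L4/5"): 0.10,
}

# layerwise unitary-EPSP (v_con) matrix interpolated onto NCD band midpoints
_V_LAYER_MIDS = (0.195, 0.33, 0.42, 0.635, 0.90)
_V_LAYER = np.array(
    [  # pre: L2/3, L4, L5A, L5B, L6 x post same
        [0.55, 0.45, 0.40, 0.35, 0.30],
        [0.70, 0.60, 0.45, 0.40, 0.30],
        [0.45, 0.45, 0.50, 0.45, 0.35],
        [0.40, 0.40, 0.45, 0.55, 0.40],
        [0.30, 0.30, 0.35, 0.40, 0.45],
    ]
)


# Overall scale of the fixture strength table: the band tables above are
# expressed relative to the strongest projection; s_con data are p x v
# products, an order of magnitude below unitary EPSPs (p ~ 0.05-0.25).
_SCON_SCALE = 0.15


def fixture_strength_rules(config: Mapping[str, Any]) -> pd.DataFrame:
    """The packaged depth-resolved strength table (synthetic fixture).

    Each row carries the strength s_con (mV) and the raw unitary EPSP
    v_raw from the interpolated layerwise matrix; decomposition into
    (v_con, p_con) happens at sampling time.
    """
    rows = []
    for table in (_EE_SCON, _PT_SCON, _EI_SCON):
        for (pre_b, post_cls, post_b), s in table.items():
            pre_lo, pre_hi = _BANDS[pre_b]
            post_lo, post_hi = (_IBANDS if post_cls in ("PV", "SOM") else _BANDS)[post_b]
            pre_mid = (pre_lo + pre_hi) / 2
            post_mid = (post_lo + post_hi) / 2
            v_raw = float(interp_vcon(_V_LAYER_MIDS, _V_LAYER, pre_mid, post_mid))
            if table is _PT_SCON:
                pc = "PT"
            elif table is _EI_SCON:
                pc = "E"  # all excitatory classes drive interneurons
            else:
                # IT outputs; in L6 both IT and CT project locally (no PT
                # there, so "E" keeps the IT->PT projection unidirectional)
                pc = "E" if pre_b == "L6" else "IT"
            rows.append(
                (pc, pre_lo, pre_hi, post_cls, post_lo, post_hi,
                 s * _SCON_SCALE, v_raw)
            )
    frame = pd.DataFrame(
        rows,
        columns=["pre_class", "pre_lo", "pre_hi", "post_class", "post_lo",
                 "post_hi", "s_con", "v_raw"],
    )
    return frame


def fixture_profiles() -> dict[tuple[str, str], RadialDensityProfile]:
    """Radial synaptic density profiles for projections onto PT cells.

    VL (MTh) input contacts PT dendrites both proximally and in the distal
    tuft; cM1 and M2 inputs are tuft-biased; local L2/3 IT input lands on
    basal/oblique (proximal) dendrites.  These stylized shapes emulate the
    sCRACM-derived density functions.
    """
    return {
        ("VL", "PT5B"): RadialDensityProfile(("VL", "PT5B"), np.array([0.3, 0.2, 0.1, 0.15, 0.25])),
        ("cM1", "PT5B"): RadialDensityProfile(("cM1", "PT5B"), np.array([0.05, 0.1, 0.15, 0.3, 0.4])),
        ("M2", "PT5B"): RadialDensityProfile(("M2", "PT5B"), np.array([0.05, 0.1, 0.15, 0.3, 0.4])),
        ("IT", "PT5B"): RadialDensityProfile(("IT", "PT5B"), np.array([0.35, 0.3, 0.2, 0.1, 0.05])),
    }


# ---------------------------------------------------------------------------


def build_fixture_network(
    scale: float,
    seed: int,
    config: Mapping[str, Any] | None = None,
) -> NetworkModel:
    """Instantiate the full pipeline at ``scale`` x neuronal density.

    All 16 populations must be present (PT5B is split into upper/lower at
    analysis time); a scale so small that any population would have fewer
    than 4 cells raises a configuration error naming the population.
    """
    if not 0.0 < scale <= 1.0:
        raise ConfigurationError("scale must be in (0, 1]")
    cfg = config or default_config()
    layers = layers_from_config(cfg)
    pops, locs, cells = build_geometry(
        layers, cfg["ratios"], cfg["cylinder"], seed=seed, scale=scale,
        merge_interneuron_layers=cfg.get("merge_interneuron_layers", ()),
    )
    for p in pops:
        if p.count < 4:
            raise ConfigurationError(
                f"scale {scale} leaves population {p.name} with {p.count} < 4 cells"
            )

    # templates: one per excitatory population (apical length adapted to the
    # population's layer span), one each for PV and SOM
    total_depth = float(cfg["cylinder"]["depth_um"])
    templates: dict[str, Any] = {}
    cell_template: dict[int, str] = {}
    for p in pops:
        if p.cell_class in ("PV", "SOM"):
            key = p.cell_class
            if key not in templates:
                templates[key] = make_template(p.cell_class, cfg)
        else:
            key = p.name
            if key not in templates:
                tpl = make_template(p.name, cfg)
                templates[key] = adapt_apical_length(tpl, (p.ncd_lo, p.ncd_hi), total_depth)
        for cid in cells.loc[cells["pop"] == p.name, "cell_id"]:
            cell_template[int(cid)] = key

    syn_cfg = cfg["synapses"]["democracy"]
    democracy = {
        key: compute_democracy_map(
            tpl,
            target_mv=float(syn_cfg["target_epsp_mv"]),
            max_factor=float(syn_cfg["max_factor"]),
            tol=float(syn_cfg["bisect_tol"]),
            settle_ms=float(syn_cfg["settle_ms"]),
            window_ms=float(syn_cfg["peak_window_ms"]),
        )
        for key, tpl in templates.items()
    }

    rules = apply_class_adjustments(fixture_strength_rules(cfg), cfg)
    ik_cfg = cfg["wiring"]["inhib_kernel"]
    kernel = InhibKernel(
        length_constant_um=float(ik_cfg["length_constant_um"]),
        base_probability=float(ik_cfg["base_probability"]),
        same_layer_only=bool(ik_cfg["same_layer_only"]),
        border_correction=bool(ik_cfg["border_correction"]),
        mc_samples=int(ik_cfg["border_mc_samples"]),
    )
    connections = sample_connections(cells, rules, kernel, cfg, seed)

    profiles = fixture_profiles()
    pre_class_of = dict(zip(cells["cell_id"], cells["cell_class"]))
    synapse_table = place_synapses(
        connections, cell_template, templates, democracy, cfg, seed,
        profiles=profiles, pre_class_of=pre_class_of,
    )
    # global weight-scale calibration factors
    wcfg = cfg["wiring"]
    cls_of = pre_class_of
    if len(synapse_table):
        pre_exc = synapse_table["pre_id"].map(cls_of).isin(["IT", "PT", "CT"])
        post_exc = synapse_table["post_id"].map(cls_of).isin(["IT", "PT", "CT"])
        sc = np.ones(len(synapse_table))
        sc[pre_exc & post_exc] = float(wcfg.get("ee_weight_scale", 1.0))
        sc[pre_exc & ~post_exc] = float(wcfg.get("ei_weight_scale", 1.0))
        sc[~pre_exc] = float(wcfg.get("ie_weight_scale", 1.0))
        synapse_table = synapse_table.assign(g_us=synapse_table["g_us"] * sc)

    lr_table = build_longrange_synapses(
        cells, cell_template, templates, democracy, cfg, seed, profiles=profiles
    )

    return NetworkModel(
        config=cfg,
        populations=pops,
        cells=cells,
        templates=templates,
        cell_template=cell_template,
        connections=connections,
        synapses=synapse_table,
        longrange={"n_units": int(cfg["longrange"]["n_units"])},
        longrange_synapses=lr_table,
        meta={"scale": scale, "connectivity_seed": seed},
    )


def run_scenario(
    preset_name: str,
    network: NetworkModel,
    input_seeds: Sequence[int],
    duration_ms: float = 4000.0,
    warmup_ms: float = 1000.0,
    record_voltage_cells: Sequence[int] = (),
) -> tuple[list[SimulationResult], pd.DataFrame]:
    """Run one preset over a set of input seeds.

    Returns the per-seed results and a pooled per-population rate summary
    (warm-up excluded).  A failing seed is recorded in the summary's attrs
    under ``failures`` and skipped.
    """
    from .analysis import population_rates

    preset = scenario_preset(network.config, preset_name)
    results: list[SimulationResult] = []
    failures: list[tuple[int, str]] = []
    frames = []
    for s in input_seeds:
        cfg = SimulationConfig(
            duration_ms=duration_ms,
            warmup_ms=warmup_ms,
            connectivity_seed=int(network.meta.get("connectivity_seed", 0)),
            input_seed=int(s),
            scenario=preset_name,
            record_voltage_cells=record_voltage_cells,
        )
        rates = scenario_rates(network, preset, int(s))
        try:
            res = run_simulation(
                network, cfg, longrange_rates=rates,
                ih_fraction=float(preset["ih_fraction"]),
                k_scale=float(preset["k_scale"]),
            )
        except (FloatingPointError, RuntimeError) as exc:
            failures.append((int(s), str(exc)))
            continue
        results.append(res)
        summary = population_rates(network, res, epoch=(warmup_ms, duration_ms))
        summary["input_seed"] = int(s)
        frames.append(summary)
    pooled = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["pop", "mean_hz", "input_seed"])
    )
    pooled.attrs["failures"] = failures
    pooled.attrs["scenario"] = preset_name
    return results, pooled


def run_grid(
    grid: GridSpec,
    network: NetworkModel,
    duration_ms: float = 3000.0,
    warmup_ms: float = 1000.0,
) -> pd.DataFrame:
    """MTh x NA exploration: mean L5B-resolved rates per grid combination."""
    from .analysis import mean_rate_of

    lr = network.config["longrange"]
    n_units = int(lr["n_units"])
    spont = tuple(lr["spontaneous_rate_hz"])
    by_region = lr.get("spontaneous_rate_by_region", {})
    rows = []
    for mth, ih in itertools.product(grid.mth_levels, grid.na_levels):
        for s in grid.input_seeds:
            rates = {}
            for region in REGIONS:
                if region == "VL":
                    if mth is None:
                        continue
                    rates["VL"] = assign_rates("VL", (0.0, float(mth)), n_units, int(s))
                else:
                    rng = tuple(by_region.get(region, spont))
                    rates[region] = assign_rates(region, rng, n_units, int(s))
            rates["INH"] = assign_rates("INH", spont, n_units, int(s))
            cfg = SimulationConfig(
                duration_ms=duration_ms, warmup_ms=warmup_ms,
                connectivity_seed=int(network.meta.get("connectivity_seed", 0)),
                input_seed=int(s), scenario=f"grid_mth{mth}_ih{ih}",
            )
            res = run_simulation(network, cfg, longrange_rates=rates,
                                 ih_fraction=float(ih), k_scale=1.0)
            epoch = (warmup_ms, duration_ms)
            rows.append({
                "mth_hz": np.nan if mth is None else float(mth),
                "ih_fraction": float(ih),
                "input_seed": int(s),
                "L5B": mean_rate_of(network, res, ["IT5B", "PT5B"], epoch),
                "IT5B": mean_rate_of(network, res, ["IT5B"], epoch),
                "PT5B": mean_rate_of(network, res, ["PT5B"], epoch),
                "PT5B_upper": mean_rate_of(network, res, ["PT5B_upper"], epoch),
                "PT5B_lower": mean_rate_of(network, res, ["PT5B_lower"], epoch),
            })
    return pd.DataFrame(rows)


def readiness_check(pooled: pd.DataFrame, pooled_low_ih: pd.DataFrame) -> dict[str, bool]:
    """The two rate-readiness criteria used during model tuning.

    1. physiologically reasonable rates: excitatory populations ~0.1-10 Hz
       at baseline I_h (0.1-30 Hz at low I_h), inhibitory 5-40 Hz (5-80).
    2. PT5B rates increase from high to low I_h.
    """
    def band(frame, pops, lo, hi):
        sub = frame[frame["pop"].isin(pops)]["mean_hz"]
        return bool(len(sub)) and bool((sub.between(lo, hi)).mean() >= 0.75)

    exc = ["IT2/3", "IT4", "IT5A", "IT5B", "IT6", "CT6", "PT5B"]
    inh = ["PV2/3", "PV5A", "PV5B", "PV6", "SOM2/3", "SOM5A", "SOM5B", "SOM6"]
    pt_hi = pooled[pooled["pop"] == "PT5B"]["mean_hz"].mean()
    pt_lo = pooled_low_ih[pooled_low_ih["pop"] == "PT5B"]["mean_hz"].mean()
    return {
        "exc_rates_reasonable": band(pooled, exc, 0.05, 10.0),
        "inh_rates_reasonable": band(pooled, inh, 1.0, 40.0),
        "pt5b_increases_with_na": bool(pt_lo > pt_hi),
    }


def generate_synthetic_observables(
    spec: Mapping[str, Any], seed: int
) -> dict[str, Any]:
    """Synthetic spikes/currents/LFP fixtures for testing the observables.

    ``spec`` declares per-population rates, optional oscillatory modulation
    and current amplitudes, e.g.::

        {"duration_ms": 4000, "fs_hz": 1000,
         "populations": [
             {"name": "PT5B", "n": 20, "rate_hz": 10, "osc_hz": 40,
              "osc_depth": 0.8, "current_amp": 1.0}]}

    Returns spike trains (inhomogeneous Poisson with sinusoidal rate
    modulation), per-compartment current traces (one compartment per cell,
    sinusoid + white noise scaled by ``current_amp``), and the composite
    LFP-like trace obtained by summing all currents.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(99,)))
    duration = float(spec.get("duration_ms", 4000.0))
    fs = float(spec.get("fs_hz", 1000.0))
    n_t = int(duration / 1000.0 * fs)
    t = np.arange(n_t) / fs  # seconds
    spikes = []
    currents = []
    pop_of_comp = []
    for pop in spec.get("populations", ()):
        name = pop["name"]
        n = int(pop["n"])
        rate = float(pop.get("rate_hz", 5.0))
        osc = float(pop.get("osc_hz", 0.0))
        depth = float(pop.get("osc_depth", 0.0))
        amp = float(pop.get("current_amp", 1.0))
        noise = float(pop.get("noise", 0.1))
        for i in range(n):
            lam = rate * (1.0 + depth * np.sin(2 * np.pi * osc * t)) if osc else np.full(n_t, rate)
            p = np.clip(lam / fs, 0, 1)
            spk = np.nonzero(rng.random(n_t) < p)[0] / fs * 1000.0
            spikes.append(pd.DataFrame({"pop": name, "cell": f"{name}_{i}", "t_ms": spk}))
            phase = rng.uniform(0, 2 * np.pi)
            if osc:
                cur = amp * np.sin(2 * np.pi * osc * t + 0.1 * phase)
            else:
                cur = np.zeros(n_t)
            cur = cur + noise * amp * rng.standard_normal(n_t)
            currents.append(cur)
            pop_of_comp.append(name)
    cur_arr = np.array(currents).T if currents else np.zeros((n_t, 0))
    return {
        "t_ms": t * 1000.0,
        "spikes": pd.concat(spikes, ignore_index=True) if spikes else pd.DataFrame(),
        "currents": cur_arr,
        "pop_of_comp": np.array(pop_of_comp),
        "lfp": cur_arr.sum(axis=1),
        "fs_hz": fs,
    }
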