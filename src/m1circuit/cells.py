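"""Reduced conductance-based cell templates for the M1 cell classes.

Seven excitatory classes (IT2/3, IT4, IT5A, IT5B, IT6, CT6, PT5B) and two
interneuron classes (PV, SOM) are represented by few-compartment trees
(3-8 compartments) carrying Hodgkin-Huxley channels: Na, Kdr, Ka, Kd, HCN,
CaL, CaN, KCa and leak.  Channel kinetics are shared across classes; class
identity lives in the morphology and the per-compartment conductance
densities, which are calibrated so each class reproduces its target f-I
slope and rheobase.  Template sharing follows the class catalogue: the
upper-IT parameter set serves L2/3 and L4 IT cells, the deep-IT set serves
IT5A/IT5B/IT6, and CT6 has its own calibration; IT5A and PT5B use the
detailed 8-compartment trees.

Neuromodulation hooks: ``ih_fraction`` scales the HCN conductance of PT
cells (the model's proxy for noradrenergic tone; 1.0 = in vitro baseline),
and ``k_scale`` scales all voltage-gated K+ conductances of excitatory
cells (the NA-R-block manipulation).  The PT HCN channel carries a shunt
conductance proportional to its activation, which lets rising I_h switch
from net excitation to net inhibition as synaptic input grows.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .config import ConfigurationError

__all__ = [
    "Compartment",
    "ChannelSpec",
    "CellTemplate",
    "make_template",
    "adapt_apical_length",
    "set_neuromodulation",
    "fi_curve",
    "calibrate_fi",
    "CHANNEL_NAMES",
    "K_CHANNELS",
    "EXC_CLASSES",
    "INH_CLASSES",
]

CHANNEL_NAMES = ("leak", "Na", "Kdr", "Ka", "Kd", "HCN", "CaL", "CaN", "KCa")
K_CHANNELS = ("Kdr", "Ka", "Kd", "KCa")
EXC_CLASSES = ("IT2/3", "IT4", "IT5A", "IT5B", "IT6", "CT6", "PT5B")
INH_CLASSES = ("PV", "SOM")
APICAL_ROLES = ("apical_trunk", "apical_tuft")


@dataclass(frozen=True)
class Compartment:
    """One cylindrical compartment of a reduced tree."""

    comp_id: int
    parent_id: int  # -1 for the root (soma)
    name: str
    role: str  # soma | axon | basal | apical_trunk | apical_tuft
    length: float  # um
    diameter: float  # um

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ConfigurationError(f"compartment {self.name}: non-positive dimensions")


@dataclass(frozen=True)
class ChannelSpec:
    """Per-compartment conductance density for one channel."""

    channel: str
    gbar: float  # S/cm^2

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_NAMES:
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        if self.gbar < 0:
            raise ConfigurationError(f"{self.channel}: negative gbar")


@dataclass(frozen=True)
class CellTemplate:
    """Compartment tree + channel densities + modulation state for one class."""

    class_name: str
    template_name: str
    compartments: tuple[Compartment, ...]
    # channel name -> per-compartment gbar array (S/cm^2), baseline values
    gbar: Mapping[str, np.ndarray]
    biophysics: Mapping[str, float]
    fi_target: tuple[float, float]  # (slope Hz/nA, rheobase pA)
    detailed: bool = False
    ih_class: bool = False  # HCN modulation (PT) applies to this template
    ih_fraction: float = 1.0
    k_scale: float = 1.0
    hcn_shunt: Mapping[str, float] = field(default_factory=dict)
    calibration: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_tree(self.compartments)
        if not 0.0 < self.ih_fraction <= 2.0:
            raise ConfigurationError("ih_fraction must be in (0, 2]")
        if self.k_scale < 0:
            raise ConfigurationError("k_scale must be >= 0")

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    @property
    def is_excitatory(self) -> bool:
        return self.class_name in EXC_CLASSES

    def effective_gbar(self, channel: str) -> np.ndarray:
        """Baseline gbar with neuromodulation and calibration scales applied."""
        g = np.asarray(self.gbar.get(channel, np.zeros(self.n_comp)), dtype=float).copy()
        cal = self.calibration or {}
        if channel == "leak":
            g *= float(cal.get("leak_scale", 1.0))
        if channel == "KCa":
            g *= float(cal.get("adapt_scale", 1.0))
        if channel == "HCN" and self.ih_class:
            g *= self.ih_fraction
        if channel in K_CHANNELS and self.is_excitatory:
            g *= self.k_scale
        return g

    def apical_comp_ids(self) -> list[int]:
        return [c.comp_id for c in self.compartments if c.role in APICAL_ROLES]

    def apical_extent(self) -> float:
        """Maximum apical path length from the soma, um."""
        return max(
            (_path_length(self.compartments, c.comp_id) for c in self.compartments
             if c.role in APICAL_ROLES),
            default=0.0,
        )

    def path_distance(self, comp_id: int) -> float:
        """Path distance from the soma to the *midpoint* of a compartment, um."""
        comp = self.compartments[comp_id]
        return _path_length(self.compartments, comp_id) - 0.5 * comp.length


def _check_tree(comps: Sequence[Compartment]) -> None:
    roots = [c for c in comps if c.parent_id < 0]
    if len(roots) != 1:
        raise ConfigurationError("template must have exactly one root compartment")
    for c in comps:
        if c.comp_id != comps.index(c):
            raise ConfigurationError("comp_id must equal list position")
        if c.parent_id >= c.comp_id:
            raise ConfigurationError("parents must precede children (no cycles)")


def _path_length(comps: Sequence[Compartment], comp_id: int) -> float:
    """Path length from the root center to the distal end of ``comp_id``."""
    total = 0.0
    i = comp_id
    while i >= 0:
        c = comps[i]
        if c.role != "soma":
            total += c.length
        i = c.parent_id
    return total


def make_template(class_name: str, config: Mapping[str, Any]) -> CellTemplate:
    """Build the calibrated template for one of the 9 model cell classes."""
    cells_cfg = config["cells"]
    mapping = cells_cfg["class_templates"]
    if class_name not in mapping:
        raise ConfigurationError(
            f"unknown cell class {class_name!r}; known: {sorted(mapping)}"
        )
    tname = mapping[class_name]
    tcfg = cells_cfg["templates"][tname]

    comps: list[Compartment] = []
    name_to_id: dict[str, int] = {}
    for i, c in enumerate(tcfg["compartments"]):
        pid = -1 if c["parent"] is None else name_to_id[c["parent"]]
        comps.append(
            Compartment(
                comp_id=i, parent_id=pid, name=c["name"], role=c["role"],
                length=float(c["L"]), diameter=float(c["diam"]),
            )
        )
        name_to_id[c["name"]] = i

    n = len(comps)
    chan_cfg = tcfg["channels"]
    gbar: dict[str, np.ndarray] = {ch: np.zeros(n) for ch in CHANNEL_NAMES}
    for comp in comps:
        # channel table may be keyed by compartment name or by role
        block = chan_cfg.get(comp.name, chan_cfg.get(comp.role, {}))
        for ch, g in block.items():
            ChannelSpec(ch, float(g))  # validates
            gbar[ch][comp.comp_id] = float(g)

    fi = tcfg.get("fi_target", {})
    return CellTemplate(
        class_name=class_name,
        template_name=tname,
        compartments=tuple(comps),
        gbar={k: v for k, v in gbar.items()},
        biophysics=dict(cells_cfg["biophysics"]),
        fi_target=(float(fi.get("slope_hz_per_na", 0.0)), float(fi.get("rheobase_pa", 0.0))),
        detailed=bool(tcfg.get("detailed", False)),
        ih_class=bool(tcfg.get("ih_class", False)),
        hcn_shunt=dict(tcfg.get("hcn_shunt", {})),
        calibration=dict(tcfg.get("calibration", {})),
    )


def adapt_apical_length(
    template: CellTemplate,
    layer_span: tuple[float, float],
    total_depth: float,
) -> CellTemplate:
    """Rescale the apical tree so the soma-to-pia extent matches the layer.

    The target extent is the layer's mean depth in um (midpoint of the NCD
    span times the cortical depth).  All apical compartments are scaled by a
    common factor, so rescaling back to the original depth recovers the
    original lengths.  Non-apical sections are unchanged.
    """
    target = 0.5 * (layer_span[0] + layer_span[1]) * total_depth
    extent = template.apical_extent()
    if extent <= 0:
        warnings.warn(
            f"template {template.template_name} has no apical section; "
            "apical-length adaptation skipped"
        )
        return template
    factor = target / extent
    new_comps = tuple(
        dataclasses.replace(c, length=c.length * factor) if c.role in APICAL_ROLES else c
        for c in template.compartments
    )
    return dataclasses.replace(template, compartments=new_comps)


def set_neuromodulation(
    template: CellTemplate,
    ih_fraction: float,
    k_scale: float,
    allow_interneuron: bool = False,
) -> CellTemplate:
    """Return the template with neuromodulation scales applied.

    ``ih_fraction`` multiplies HCN conductance (effective only on the
    PT/ih-class template unless the template is configured otherwise);
    ``k_scale`` multiplies the voltage-gated K+ conductances of excitatory
    classes.  Scaling K+ on interneurons is rejected unless explicitly
    overridden, matching the all-excitatory scope of the manipulation.
    """
    if ih_fraction <= 0 or k_scale <= 0:
        raise ValueError("ih_fraction and k_scale must be positive")
    if k_scale != 1.0 and not template.is_excitatory and not allow_interneuron:
        raise ValueError(
            f"k_scale applies to excitatory classes only; {template.class_name} "
            "is an interneuron (pass allow_interneuron=True to override)"
        )
    return dataclasses.replace(template, ih_fraction=ih_fraction, k_scale=k_scale)


def fi_curve(
    template: CellTemplate,
    currents_pa: Sequence[float],
    duration_ms: float = 1000.0,
    settle_ms: float = 200.0,
    dt_ms: float = 0.025,
) -> tuple[float, float, np.ndarray]:
    """f-I characterisation by somatic current steps.

    Returns (slope Hz/nA, rheobase pA, rates Hz).  Rheobase is the smallest
    injected current evoking at least one spike; the slope is the
    least-squares slope of rate vs current over the suprathreshold points.
    If no current spikes, the rheobase is reported as a sentinel one step
    above the largest tested current.
    """
    from .engine import simulate_single_cell  # deferred: engine imports numba

    currents = np.asarray(sorted(currents_pa), dtype=float)
    if duration_ms < 1000.0:
        raise ValueError("duration must be >= 1000 ms for a stable rate estimate")
    rates = np.empty(len(currents))
    for i, i_pa in enumerate(currents):
        res = simulate_single_cell(
            template,
            duration_ms=settle_ms + duration_ms,
            dt_ms=dt_ms,
            i_inj_na=i_pa / 1000.0,
            i_inj_start_ms=settle_ms,
        )
        n_spk = int(np.sum(res.spikes[:, 1] >= settle_ms))
        rates[i] = n_spk / (duration_ms / 1000.0)

    above = np.nonzero(rates > 0)[0]
    if len(above) == 0:
        step = currents[-1] - currents[-2] if len(currents) > 1 else currents[-1]
        return 0.0, float(currents[-1] + step), rates
    rheobase = float(currents[above[0]])
    supra = above
    if len(supra) >= 2:
        x_na = currents[supra] / 1000.0
        slope = float(np.polyfit(x_na, rates[supra], 1)[0])
    else:
        slope = 0.0
    return slope, rheobase, rates


def calibrate_fi(
    template: CellTemplate,
    max_iter: int = 8,
    tol: float = 0.05,
    duration_ms: float = 1000.0,
) -> CellTemplate:
    """Tune leak_scale and adapt_scale so the f-I curve matches fi_target.

    Rheobase is controlled by the leak conductance (input resistance),
    f-I slope by the Ca-dependent K+ adaptation conductance; the two are
    nearly orthogonal, so alternating proportional updates converge in a
    few iterations.  Returns the template with updated calibration scales.
    """
    target_slope, target_rheo = template.fi_target
    if target_slope <= 0 or target_rheo <= 0:
        raise ValueError("template has no f-I target")
    cal = dict(template.calibration or {})
    cal.setdefault("leak_scale", 1.0)
    cal.setdefault("adapt_scale", 1.0)
    tpl = dataclasses.replace(template, calibration=cal)
    lo, hi = 0.5 * target_rheo, 2.0 * target_rheo
    currents = np.unique(np.round(np.linspace(lo, hi, 10)))
    for _ in range(max_iter):
        slope, rheo, _ = fi_curve(tpl, currents, duration_ms=duration_ms)
        ok_r = abs(rheo - target_rheo) <= tol * target_rheo + 0.51 * (currents[1] - currents[0])
        ok_s = slope > 0 and abs(slope - target_slope) <= tol * target_slope
        if ok_r and ok_s:
            break
        cal = dict(tpl.calibration)
        if rheo > 0:
            cal["leak_scale"] = cal["leak_scale"] * (target_rheo / rheo) ** 0.9
        if slope > 0:
            cal["adapt_scale"] = min(
                50.0, cal["adapt_scale"] * (slope / target_slope) ** 0.9
            )
        tpl = dataclasses.replace(tpl, calibration=cal)
    return tpl
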