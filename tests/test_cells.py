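"""Cell templates: catalogue, apical adaptation, f-I and neuromodulation."""

import dataclasses

import numpy as np
import pytest

from m1circuit.cells import (
    adapt_apical_length,
    fi_curve,
    make_template,
    set_neuromodulation,
)
from m1circuit.config import ConfigurationError


def test_unknown_class_rejected(cfg):
    with pytest.raises(ConfigurationError):
        make_template("granule", cfg)


def test_template_sharing(cfg):
    """IT2/3 and CT6 share the upper-IT channel parameter set; deep IT
    classes share the deep set; IT5A and PT5B use detailed trees."""
    it23 = make_template("IT2/3", cfg)
    it4 = make_template("IT4", cfg)
    ct6 = make_template("CT6", cfg)
    assert it23.template_name == it4.template_name == "IT_upper"
    # CT6 carries the same soma channel densities as the upper-IT set
    np.testing.assert_allclose(
        make_template("CT6", cfg).gbar["Na"][0], it23.gbar["Na"][0]
    )
    it5b = make_template("IT5B", cfg)
    it6 = make_template("IT6", cfg)
    assert it5b.template_name == it6.template_name == "IT_deep"
    assert make_template("IT5A", cfg).detailed
    assert make_template("PT5B", cfg).detailed
    assert ct6.fi_target == (69.0, 298.0)


def test_interneuron_three_compartments(cfg):
    assert make_template("PV", cfg).n_comp == 3
    assert make_template("SOM", cfg).n_comp == 3


def test_pt_hot_zone_and_hcn(cfg, pt_template):
    """PT carries dominant HCN and elevated Ca channels in the tuft."""
    tuft = [c.comp_id for c in pt_template.compartments if c.role == "apical_tuft"]
    soma_cal = pt_template.gbar["CaL"][0]
    assert all(pt_template.gbar["CaL"][c] > soma_cal for c in tuft)
    it = make_template("IT5B", cfg)
    assert pt_template.gbar["HCN"].sum() > it.gbar["HCN"].sum()


def test_apical_adaptation_sets_extent(pt_template):
    adapted = adapt_apical_length(pt_template, (0.2, 0.6), total_depth=1250.0)
    assert adapted.apical_extent() == pytest.approx(0.4 * 1250.0)
    # non-apical sections untouched
    for a, b in zip(pt_template.compartments, adapted.compartments):
        if a.role not in ("apical_trunk", "apical_tuft"):
            assert a.length == b.length


def test_apical_adaptation_round_trip(pt_template):
    orig_extent = pt_template.apical_extent()
    there = adapt_apical_length(pt_template, (0.3, 0.5), 1350.0)
    span = (orig_extent / 1350.0, orig_extent / 1350.0)  # midpoint = original
    back = adapt_apical_length(there, span, 1350.0)
    for a, b in zip(pt_template.compartments, back.compartments):
        assert a.length == pytest.approx(b.length)


def test_apical_adaptation_without_apical_warns():
    from tests.conftest import passive_template

    tpl = passive_template(n_comp=1)
    with pytest.warns(UserWarning):
        out = adapt_apical_length(tpl, (0.1, 0.3), 1350.0)
    assert out is tpl


def test_apical_adaptation_changes_firing(it_deep_template):
    """The same parameter set adapted to layers of different mean depth
    produces (slightly) different firing responses."""
    shallow = adapt_apical_length(it_deep_template, (0.15, 0.25), 1350.0)
    deep = adapt_apical_length(it_deep_template, (0.6, 0.9), 1350.0)
    _, _, r_shallow = fi_curve(shallow, [150.0, 200.0], duration_ms=1000.0)
    _, _, r_deep = fi_curve(deep, [150.0, 200.0], duration_ms=1000.0)
    assert not np.array_equal(r_shallow, r_deep)


def test_neuromodulation_identity_and_presets(pt_template):
    same = set_neuromodulation(pt_template, 1.0, 1.0)
    np.testing.assert_allclose(same.effective_gbar("HCN"), pt_template.effective_gbar("HCN"))
    moved = set_neuromodulation(pt_template, 0.25, 1.0)
    np.testing.assert_allclose(
        moved.effective_gbar("HCN"), 0.25 * pt_template.effective_gbar("HCN")
    )
    nar = set_neuromodulation(pt_template, 1.0, 1.5)
    np.testing.assert_allclose(nar.effective_gbar("Kdr"), 1.5 * pt_template.effective_gbar("Kdr"))


def test_k_scale_rejected_on_interneurons(cfg):
    pv = make_template("PV", cfg)
    with pytest.raises(ValueError):
        set_neuromodulation(pv, 1.0, 1.5)
    # explicit override allowed
    out = set_neuromodulation(pv, 1.0, 1.5, allow_interneuron=True)
    assert out.k_scale == 1.5


def test_subthreshold_current_is_silent(it_deep_template):
    slope, rheo, rates = fi_curve(it_deep_template, [20.0, 50.0], duration_ms=1000.0)
    assert rates[0] == 0.0 and rates[1] == 0.0


def test_fi_recovery_all_templates(cfg):
    """Each template's measured (slope, rheobase) is within 15% of target."""
    seen = set()
    for cls in ("IT2/3", "IT5A", "IT5B", "CT6", "PT5B", "PV", "SOM"):
        tpl = make_template(cls, cfg)
        if tpl.template_name in seen:
            continue
        seen.add(tpl.template_name)
        ts, tr = tpl.fi_target
        currents = np.unique(np.round(np.linspace(0.5 * tr, 2.0 * tr, 10)))
        slope, rheo, _ = fi_curve(tpl, currents, duration_ms=1000.0)
        assert abs(slope - ts) <= 0.15 * ts, (cls, slope, ts)
        assert abs(rheo - tr) <= 0.15 * tr, (cls, rheo, tr)


def test_k_scale_never_increases_rates(it_deep_template):
    """+50% K+ conductance does not increase the f-I rate at any current."""
    currents = [80.0, 150.0, 250.0]
    _, _, base = fi_curve(it_deep_template, currents, duration_ms=1000.0)
    scaled = set_neuromodulation(it_deep_template, 1.0, 1.5)
    _, _, high_k = fi_curve(scaled, currents, duration_ms=1000.0)
    assert np.all(high_k <= base)


def test_monotone_ih_effect_under_drive(pt_template):
    """With fixed synaptic bombardment, PT fires at least as much at low
    I_h (high NA) as at the in vitro baseline."""
    from m1circuit.engine import simulate_single_cell
    from m1circuit.synapses import compute_democracy_map

    dmap = compute_democracy_map(pt_template)
    rng = np.random.default_rng(3)
    events = []
    for comp in (2, 3, 4, 5, 6):
        g = dmap.weight_to_g(0.5, comp) / 2
        for t in np.sort(rng.uniform(200, 2200, 500)):
            events.append((float(t), comp, "AMPA", g))
            events.append((float(t), comp, "NMDA", g))
    g_in = dmap.weight_to_g(0.6, 0)
    for t in np.sort(rng.uniform(200, 2200, 1400)):
        events.append((float(t), 0, "GABAA_fast", 2 * g_in))
    events.sort()
    n_low = len(simulate_single_cell(
        set_neuromodulation(pt_template, 0.25, 1.0), 2400.0, events=events).spikes)
    n_high = len(simulate_single_cell(
        set_neuromodulation(pt_template, 1.0, 1.0), 2400.0, events=events).spikes)
    assert n_low >= n_high
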