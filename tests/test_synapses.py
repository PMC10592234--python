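"""Synaptic democracy, radial profiles, placement rules and receptor mixes."""

import numpy as np
import pandas as pd
import pytest

from m1circuit.synapses import (
    RadialDensityProfile,
    compute_democracy_map,
    epsp_peak,
    nmda_mg_factor,
    profile_from_map,
)
from tests.conftest import passive_template


def test_soma_factor_is_unity(pt_template):
    dmap = compute_democracy_map(pt_template)
    assert dmap.factors[0] == pytest.approx(1.0)


def test_distal_tuft_capped_at_four(pt_template):
    dmap = compute_democracy_map(pt_template)
    tuft = [c.comp_id for c in pt_template.compartments if c.role == "apical_tuft"]
    assert any(dmap.raw_factors[c] > 4.0 for c in tuft)
    assert all(dmap.factors[c] == 4.0 for c in tuft if dmap.raw_factors[c] > 4.0)
    assert np.all(dmap.factors <= 4.0)


def test_passive_single_compartment_factor_unity():
    tpl = passive_template(n_comp=1)
    dmap = compute_democracy_map(tpl)
    np.testing.assert_allclose(dmap.factors, 1.0, rtol=0.02)


def test_democracy_epsp_invariant(pt_template):
    """Unitary activation gives a somatic EPSP within 10% of v_con on
    uncapped compartments and at most v_con on capped ones."""
    dmap = compute_democracy_map(pt_template)
    v_con = 0.7
    for comp in range(pt_template.n_comp):
        g = dmap.weight_to_g(v_con, comp)
        peak = epsp_peak(pt_template, comp, g)
        if dmap.raw_factors[comp] <= 4.0:
            assert abs(peak - v_con) <= 0.10 * v_con, (comp, peak)
        else:
            assert peak <= v_con + 1e-6


@pytest.mark.parametrize(
    "amp,length,expected",
    [
        (np.array([[2.0, 2.0], [4.0, 4.0]]), np.array([[1.0, 1.0], [2.0, 2.0]]), [0.5, 0.5]),
        (np.array([[1.0, 1.0], [0.0, 0.0]]), np.ones((2, 2)), [1.0, 0.0]),
        (np.ones((3, 2)), np.ones((3, 2)), [1 / 3] * 3),
    ],
)
def test_profile_from_map(amp, length, expected):
    prof = profile_from_map(amp, length)
    np.testing.assert_allclose(prof.weights, expected)


def test_profile_rejects_amplitude_without_dendrite():
    with pytest.raises(ValueError):
        profile_from_map(np.array([[1.0]]), np.array([[0.0]]))


def test_nmda_mg_block():
    assert nmda_mg_factor(0.0, 1.0) == pytest.approx(1.0 / 1.28)
    assert nmda_mg_factor(-70.0, 0.0) == pytest.approx(1.0)
    v = np.linspace(-90, 20, 50)
    f = nmda_mg_factor(v, 1.0)
    assert np.all(np.diff(f) > 0)  # strictly increasing in V
    with pytest.raises(ValueError):
        nmda_mg_factor(0.0, -1.0)


def _syn_with_pre_class(net, cls):
    pre_of = net.cells.set_index("cell_id")["cell_class"]
    syn = net.synapses
    return syn[syn["pre_id"].map(pre_of) == cls]


def test_pv_contacts_perisomatic(small_network):
    """PV outputs onto excitatory cells land within 50 um of the soma."""
    net = small_network
    cls_of = net.cells.set_index("cell_id")["cell_class"]
    pv_rows = _syn_with_pre_class(net, "PV")
    exc_targets = pv_rows[pv_rows["post_id"].map(cls_of).isin(["IT", "PT", "CT"])]
    assert len(exc_targets) > 0
    for post_id, grp in exc_targets.groupby("post_id"):
        tpl = net.templates[net.cell_template[post_id]]
        for comp in grp["comp"].unique():
            assert tpl.path_distance(int(comp)) <= 50.0


def test_som_receptor_mix(small_network):
    """SOM->E is 90% slow GABA_A / 10% GABA_B by weight; SOM->I slow only."""
    net = small_network
    cls_of = net.cells.set_index("cell_id")["cell_class"]
    som_rows = _syn_with_pre_class(net, "SOM")
    post_cls = som_rows["post_id"].map(cls_of)
    to_e = som_rows[post_cls.isin(["IT", "PT", "CT"])]
    to_i = som_rows[~post_cls.isin(["IT", "PT", "CT"])]
    assert set(to_e["receptor"]) == {"GABAA_slow", "GABAB"}
    w = to_e.groupby("receptor")["weight_mv"].sum()
    assert w["GABAB"] / (w["GABAB"] + w["GABAA_slow"]) == pytest.approx(0.10, abs=1e-9)
    assert set(to_i["receptor"]) == {"GABAA_slow"}
    # SOM->E contacts live on apical sections
    for post_id, grp in to_e.groupby("post_id"):
        tpl = net.templates[net.cell_template[post_id]]
        apical = set(tpl.apical_comp_ids())
        assert set(grp["comp"].astype(int)) <= apical


def test_contact_counts_and_weight_sum(small_network):
    """5 contacts per connection onto detailed templates, 1 otherwise;
    summed per-connection weight equals v_con."""
    net = small_network
    exc = net.connections[net.connections["kind"] == "exc"]
    syn = net.synapses
    sample = exc.sample(40, random_state=0)
    for conn in sample.itertuples():
        rows = syn[(syn["pre_id"] == conn.pre_id) & (syn["post_id"] == conn.post_id)]
        tpl = net.templates[net.cell_template[conn.post_id]]
        n_contacts = len(rows[rows["receptor"] == "AMPA"])
        assert n_contacts == (5 if tpl.detailed else 1)
        assert rows["weight_mv"].sum() == pytest.approx(conn.v_con)


def test_exc_synapses_split_ampa_nmda(small_network):
    syn = small_network.synapses
    exc = syn[syn["kind"] == "exc"]
    by_rec = exc.groupby("receptor")["weight_mv"].sum()
    assert by_rec["AMPA"] == pytest.approx(by_rec["NMDA"])


def test_placement_follows_radial_profile(cfg, pt_template):
    """Contact histogram over apical compartments follows the profile."""
    from m1circuit.synapses import _comp_for_radial_position

    rng = np.random.default_rng(0)
    profile = RadialDensityProfile(("VL", "PT5B"), np.array([0.5, 0.1, 0.1, 0.1, 0.2]))
    nb = len(profile.weights)
    n = 20000
    bins = rng.choice(nb, size=n, p=profile.weights)
    pos = (bins + rng.random(n)) / nb
    comps = _comp_for_radial_position(pt_template, pos)
    # chi-square of the empirical compartment histogram against the exact
    # expectation obtained by mapping a fine position grid through the same
    # compartment assignment
    from scipy import stats

    grid = np.linspace(0, 1, 20001)[:-1] + 0.5 / 20000
    grid_comps = _comp_for_radial_position(pt_template, grid)
    density = np.repeat(profile.weights * 1.0 / (1.0 / nb), nb)  # piecewise
    weights_fine = profile.weights[np.minimum((grid * nb).astype(int), nb - 1)]
    expected = pd.Series(0.0, index=np.unique(grid_comps))
    for c, w in zip(grid_comps, weights_fine):
        expected[c] += w
    expected = expected / expected.sum() * n
    observed = pd.Series(comps).value_counts().reindex(expected.index, fill_value=0)
    p = stats.chisquare(observed, expected).pvalue
    assert p > 0.01
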