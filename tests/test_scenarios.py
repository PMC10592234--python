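"""Scenario presets, fixture construction and synthetic observables."""

import numpy as np
import pytest

from m1circuit.config import ConfigurationError
from m1circuit.scenarios import (
    build_fixture_network,
    fixture_strength_rules,
    generate_synthetic_observables,
    scenario_preset,
    scenario_rates,
)


def test_preset_table_covers_all_conditions(cfg):
    presets = cfg["scenarios"]
    expected = {
        "quiet": (0.75, 1.0), "movement": (0.25, 1.0),
        "mth_inact_quiet": (0.75, 1.0), "mth_inact_movement": (0.25, 1.0),
        "mth_inact_movement_modified": (0.25, 1.0),
        "nar_block_quiet": (1.0, 1.0), "nar_block_movement": (1.0, 1.0),
        "nar_block_movement_modified": (1.0, 1.5),
    }
    assert set(presets) == set(expected)
    for name, (ih, ks) in expected.items():
        p = scenario_preset(cfg, name)
        assert p["ih_fraction"] == ih and p["k_scale"] == ks
    assert "VL" in presets["movement"]["increased_regions"]
    assert "VL" in presets["mth_inact_movement"]["removed_regions"]
    assert presets["mth_inact_movement_modified"]["rate_scale"] == {"cM1": 0.5, "M2": 0.5}
    with pytest.raises(ConfigurationError):
        scenario_preset(cfg, "unknown")


def test_scenario_rates_respect_presets(small_network):
    net = small_network
    cfg = net.config
    quiet = scenario_rates(net, scenario_preset(cfg, "quiet"), input_seed=0)
    move = scenario_rates(net, scenario_preset(cfg, "movement"), input_seed=0)
    inact = scenario_rates(net, scenario_preset(cfg, "mth_inact_movement"), input_seed=0)
    mod = scenario_rates(net, scenario_preset(cfg, "mth_inact_movement_modified"), 0)
    assert quiet["VL"].max() <= 5.0
    assert move["VL"].max() > 5.0 and move["VL"].max() <= 10.0
    assert "VL" not in inact
    np.testing.assert_allclose(mod["cM1"], inact["cM1"] * 0.5)
    # cortical regions carry the lower spontaneous cap
    assert quiet["S1"].max() <= 2.5


def test_fixture_rules_qualitative_wiring(cfg):
    rules = fixture_strength_rules(cfg)
    # IT -> PT rows exist; no PT -> IT/CT rows (unidirectional projection)
    assert ((rules["pre_class"] == "IT") & (rules["post_class"] == "PT")).any()
    pt_rows = rules[rules["pre_class"] == "PT"]
    assert set(pt_rows["post_class"]) <= {"PT", "PV", "SOM"}
    # strongest L2/3 input goes to the upper PT band
    l23 = rules[(rules["pre_lo"] == 0.10) & (rules["post_class"] == "PT")]
    upper = l23[l23["post_lo"] == 0.47]["s_con"].iloc[0]
    lower = l23[l23["post_lo"] == 0.635]["s_con"].iloc[0]
    assert upper > lower


def test_build_scale_guard_names_population():
    with pytest.raises(ConfigurationError, match="< 4 cells"):
        build_fixture_network(scale=0.02, seed=1)
    with pytest.raises(ConfigurationError):
        build_fixture_network(scale=1.5, seed=1)


def test_fixture_network_composition(small_network):
    net = small_network
    assert len(net.populations) == 15
    assert len(net.population_names(split_pt5b=True)) == 16
    assert all(p.count >= 4 for p in net.populations)
    # proportional counts: 8% of 10,073 within rounding slack
    assert abs(net.n_cells - 0.08 * 10073) <= 15
    up, lo = net.cells_of("PT5B_upper"), net.cells_of("PT5B_lower")
    assert len(up) + len(lo) == len(net.cells_of("PT5B"))


def test_synthetic_observables_gamma_fixture():
    spec = {"duration_ms": 8000.0, "fs_hz": 1000.0,
            "populations": [{"name": "PT5B", "n": 30, "rate_hz": 10.0,
                             "osc_hz": 40.0, "osc_depth": 0.9,
                             "current_amp": 1.0, "noise": 0.05}]}
    out = generate_synthetic_observables(spec, seed=1)
    from m1circuit.lfp import band_power

    bp = band_power(out["lfp"], fs_hz=1000.0, segment_len_s=4.0)
    bands = bp[["delta", "theta", "alpha", "beta", "gamma"]].mean()
    assert bands.idxmax() == "gamma"


def test_synthetic_observables_two_state_silhouette():
    spec = {"duration_ms": 4000.0, "fs_hz": 1000.0,
            "populations": [
                {"name": "A", "n": 8, "rate_hz": 2.0},
                {"name": "B", "n": 8, "rate_hz": 30.0},
            ]}
    out = generate_synthetic_observables(spec, seed=2)
    from m1circuit.analysis import binned_rates, latent_embedding

    spikes = out["spikes"]
    ids = {name: i for i, name in enumerate(spikes["cell"].unique())}
    arr = np.column_stack([spikes["cell"].map(ids), spikes["t_ms"]])
    groups_a = {c: np.array([i]) for c, i in ids.items() if c.startswith("A")}
    groups_b = {c: np.array([i]) for c, i in ids.items() if c.startswith("B")}
    _, ra = binned_rates(arr, {**groups_a, **groups_b}, 100.0, (0.0, 4000.0))
    # construct two "states" from the same fixture: low-rate half vs full
    x = np.vstack([ra[:, : len(groups_a)], ra[:, len(groups_a):]])
    labels = ["low"] * ra.shape[0] + ["high"] * ra.shape[0]
    traj = latent_embedding(x, labels, seed=0, n_neighbors=15, min_dist=0.3)
    assert traj.silhouette > 0.5


def test_synthetic_current_contributions_recovered():
    """Prescribed per-population current amplitudes are recovered from the
    composite trace decomposition within a few percent."""
    spec = {"duration_ms": 4000.0, "fs_hz": 1000.0,
            "populations": [
                {"name": "A", "n": 10, "osc_hz": 40.0, "osc_depth": 1.0,
                 "current_amp": 2.0, "noise": 0.0},
                {"name": "B", "n": 10, "osc_hz": 12.0, "osc_depth": 1.0,
                 "current_amp": 1.0, "noise": 0.0},
            ]}
    out = generate_synthetic_observables(spec, seed=3)
    cur = out["currents"]
    pops = out["pop_of_comp"]
    a = cur[:, pops == "A"].sum(axis=1)
    b = cur[:, pops == "B"].sum(axis=1)
    np.testing.assert_allclose(a + b, out["lfp"], rtol=1e-10)
    # variance of A's contribution reflects its 2x amplitude and 10 cells
    ratio = np.std(a) / np.std(b)
    assert ratio == pytest.approx(2.0, rel=0.35)  # phase dispersion lowers it


def test_swc_reader_round_trip(tmp_path):
    """Synthetic SWC morphology: section lengths and radial profile."""
    from m1circuit.swc import radial_length_profile, read_swc, reduced_dimensions

    swc_text = """# synthetic test morphology
1 1 0 0 0 10 -1
2 3 10 -10 0 1 1
3 3 20 -20 0 1 2
4 4 0 50 0 2 1
5 4 0 150 0 1.5 4
6 4 0 300 0 1 5
7 2 0 -40 0 0.8 1
"""
    path = tmp_path / "cell.swc"
    path.write_text(swc_text)
    swc = read_swc(path)
    dims = reduced_dimensions(swc)
    assert dims.apical_extent == pytest.approx(300.0)
    assert dims.total_apical_length == pytest.approx(50.0 + 100.0 + 150.0)
    assert dims.total_axon_length == pytest.approx(40.0)
    prof = radial_length_profile(swc, n_bins=3)
    assert prof.sum() == pytest.approx(1.0)
    assert prof[2] > 0  # distal mass present
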