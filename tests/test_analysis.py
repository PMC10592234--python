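"""Rates, estimated synaptic drive, latent dynamics and statistics."""

import numpy as np
import pandas as pd
import pytest

from m1circuit.analysis import (
    binned_rates,
    cell_rates,
    classify_enhanced_suppressed,
    compare_rates,
    esd,
    esd_input_clusters,
    esd_per_cell,
    latent_embedding,
)


def test_cell_rates_warmup_and_filter():
    spikes = np.array([[0, 500.0], [0, 1500.0], [1, 1200.0], [1, 1800.0]])
    r = cell_rates(spikes, [0, 1, 2], epoch=(1000.0, 2000.0))
    assert r[0] == pytest.approx(1.0)  # the 500-ms spike is excluded
    assert r[1] == pytest.approx(2.0)
    assert r[2] == 0.0
    rf = cell_rates(spikes, [0, 1, 2], epoch=(1000.0, 2000.0), zero_filter=True)
    assert 2 not in rf.index


def test_esd_single_contact_example(small_network):
    """One presynaptic cell at 4 Hz through one 0.5 mV contact onto one
    postsynaptic cell gives S = 2.0 mV*Hz."""
    net = small_network
    import copy

    tiny = copy.copy(net)
    tiny.synapses = pd.DataFrame(
        [{"pre_id": 0, "post_id": 1, "comp": 0, "pos": 0.5, "receptor": "AMPA",
          "weight_mv": 0.5, "g_us": 1e-4, "delay_ms": 2.0, "kind": "exc"}]
    )
    tiny.longrange_synapses = None
    spikes = np.array([[0, t] for t in np.linspace(1000.0, 1999.0, 4)])
    per_cell = esd_per_cell(tiny, spikes, (1000.0, 2000.0))
    assert per_cell["drive"].sum() == pytest.approx(2.0)
    # all rates zero -> S = 0
    per_cell0 = esd_per_cell(tiny, np.empty((0, 2)), (1000.0, 2000.0))
    assert per_cell0["drive"].sum() == 0.0


def test_esd_averages_over_postsynaptic_population(small_network):
    """With two post cells and one connected, the population S halves."""
    net = small_network
    pop = net.cells.loc[net.cells["cell_id"] == 1, "pop"].iloc[0]
    ids = net.cells_of(pop)
    import copy

    tiny = copy.copy(net)
    tiny.synapses = pd.DataFrame(
        [{"pre_id": 0, "post_id": 1, "comp": 0, "pos": 0.5, "receptor": "AMPA",
          "weight_mv": 0.5, "g_us": 1e-4, "delay_ms": 2.0, "kind": "exc"}]
    )
    tiny.longrange_synapses = None
    spikes = np.array([[0, t] for t in np.linspace(1000.0, 1999.0, 4)])
    table = esd(tiny, spikes, (1000.0, 2000.0), split_pt5b=False)
    row = table[table["post_pop"] == pop]
    assert row["esd_mv_hz"].iloc[0] == pytest.approx(2.0 / len(ids))


def test_esd_equals_brute_force_oracle(small_network):
    """Module ESD equals a per-synapse replay accumulator exactly."""
    net = small_network
    rng = np.random.default_rng(0)
    cells = rng.choice(net.cells["cell_id"].to_numpy(), 100, replace=False)
    spikes = np.column_stack([
        rng.choice(cells, 400),
        rng.uniform(1000.0, 3000.0, 400),
    ])
    epoch = (1000.0, 3000.0)
    per_cell = esd_per_cell(net, spikes, epoch)
    # brute force: iterate every synapse row, accumulate rate x weight
    rates = cell_rates(spikes, net.cells["cell_id"], epoch)
    pop_of = net.cells.set_index("cell_id")["pop"].copy()
    for sub in ("PT5B_upper", "PT5B_lower"):
        pop_of.loc[net.cells_of(sub)] = sub
    acc: dict = {}
    for row in net.synapses.itertuples():
        key = (row.post_id, pop_of[row.pre_id], row.kind)
        acc[key] = acc.get(key, 0.0) + row.weight_mv * rates[row.pre_id]
    brute = pd.Series(acc)
    got = per_cell.set_index(["post_id", "source", "kind"])["drive"]
    got = got[got != 0]
    brute = brute[brute != 0]
    assert len(got) == len(brute)
    for key, val in brute.items():
        assert got[key] == pytest.approx(val, rel=1e-12)


def test_classification_enhanced_suppressed():
    q = pd.Series({0: 1.0, 1: 7.5, 2: 4.0})
    m = pd.Series({0: 13.0, 1: 2.0, 2: 4.0})
    labels = classify_enhanced_suppressed(q, m)
    assert labels[0] == "enhanced"
    assert labels[1] == "suppressed"
    assert labels[2] == "unchanged"


def test_binned_rates():
    spikes = np.array([[0, 105.0], [0, 155.0], [1, 110.0]])
    centers, rates = binned_rates(spikes, {"a": np.array([0]), "b": np.array([1])},
                                  bin_ms=50.0, t_range=(100.0, 200.0))
    assert rates.shape == (2, 2)
    assert rates[0, 0] == pytest.approx(20.0)  # 1 spike / 1 cell / 50 ms
    assert rates[1, 1] == pytest.approx(0.0)


def test_latent_embedding_separates_states():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.05, size=(60, 16))
    b = rng.normal(1.0, 0.05, size=(60, 16))
    x = np.vstack([a, b])
    labels = ["quiet"] * 60 + ["movement"] * 60
    traj = latent_embedding(x, labels, seed=1, n_neighbors=15, min_dist=0.3)
    assert traj.silhouette > 0.8
    # permuted labels destroy the structure
    perm = list(np.random.default_rng(1).permutation(labels))
    traj_null = latent_embedding(x, perm, seed=1, n_neighbors=15, min_dist=0.3)
    assert abs(traj_null.silhouette) < 0.2
    assert traj.embedding.shape == (120, 3)
    assert np.isfinite(traj.reconstruction_r)


def test_latent_embedding_deterministic():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(50, 8))
    labels = ["a"] * 25 + ["b"] * 25
    t1 = latent_embedding(x, labels, seed=7, n_neighbors=10)
    t2 = latent_embedding(x, labels, seed=7, n_neighbors=10)
    np.testing.assert_allclose(t1.embedding, t2.embedding)


def test_esd_input_clusters_recover_profiles():
    rng = np.random.default_rng(3)
    a = rng.normal([10, 1, 1, 1], 0.3, size=(30, 4))
    b = rng.normal([1, 1, 10, 1], 0.3, size=(30, 4))
    table = pd.DataFrame(np.vstack([a, b]), columns=["IT2/3", "IT5A", "VL", "M2"])
    out = esd_input_clusters(table, seed=0)
    first, second = out["cluster"][:30], out["cluster"][30:]
    assert (first == first.iloc[0]).all()
    assert (second == second.iloc[0]).all()
    assert first.iloc[0] != second.iloc[0]


def test_compare_rates():
    a = np.ones(30)
    stat, p = compare_rates(a, a.copy())
    assert p == pytest.approx(1.0)
    lo = np.random.default_rng(0).normal(0.0, 0.1, 50)
    hi = lo + 100.0
    _, p2 = compare_rates(lo, hi)
    assert p2 < 1e-15
    _, p3 = compare_rates(lo, hi, n_comparisons=5)
    assert p3 == pytest.approx(min(1.0, p2 * 5))
    with pytest.raises(ValueError):
        compare_rates([], [1.0])
    # zero filter drops silent cells
    _, p4 = compare_rates([0.0, 0.0, 1.0], [1.0], zero_filter=True)
    assert np.isfinite(p4)
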