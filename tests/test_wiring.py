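"""Strength decomposition, adjustments, delays and connection sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m1circuit.wiring import (
    InhibKernel,
    apply_class_adjustments,
    compute_delay,
    decompose_strength,
    interp_vcon,
    rules_from_csv,
    rules_to_csv,
    sample_connections,
)


@pytest.mark.parametrize(
    "s,v_raw,v_exp,p_exp",
    [
        (0.15, 0.2, 0.3, 0.5),  # lower clip then divide
        (0.5, 2.0, 1.0, 0.5),  # upper clip then divide
        (0.0, 0.7, 0.7, 0.0),  # zero strength
    ],
)
def test_decompose_examples(s, v_raw, v_exp, p_exp):
    rule = decompose_strength(s, v_raw)
    assert rule.v_con == pytest.approx(v_exp)
    assert rule.p_con == pytest.approx(p_exp)


@given(st.floats(0.0, 3.0), st.floats(0.01, 5.0))
@settings(max_examples=200, deadline=None)
def test_decompose_invariants(s, v_raw):
    rule = decompose_strength(s, v_raw)
    assert 0.3 <= rule.v_con <= 1.0
    assert 0.0 <= rule.p_con <= 1.0
    if 0.3 <= v_raw <= 1.0 and s / v_raw <= 1.0:
        # no clipping fired: the decomposition identity holds exactly
        assert rule.p_con * rule.v_con == pytest.approx(s)


def test_decompose_rejects_bad_inputs():
    with pytest.raises(ValueError):
        decompose_strength(-0.1, 0.5)
    with pytest.raises(ValueError):
        decompose_strength(0.5, 0.0)


@pytest.mark.parametrize("d,expected", [(0.0, 2.0), (500.0, 3.0), (250.0, 2.5)])
def test_delay_law(d, expected):
    assert compute_delay(d) == pytest.approx(expected)


def test_delay_rejects_negative():
    with pytest.raises(ValueError):
        compute_delay(-1.0)


def test_vcon_interpolation_is_piecewise_linear():
    mids = [0.2, 0.5, 0.8]
    v = np.array([[0.4, 0.5, 0.6], [0.5, 0.6, 0.7], [0.6, 0.7, 0.8]])
    # at a midpoint pair, exact matrix value
    assert interp_vcon(mids, v, 0.5, 0.5) == pytest.approx(0.6)
    # halfway between midpoints, the average
    assert interp_vcon(mids, v, 0.35, 0.5) == pytest.approx(0.55)
    # clamped beyond the outermost midpoints
    assert interp_vcon(mids, v, 0.05, 0.95) == pytest.approx(0.6)


def _rule_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["pre_class", "pre_lo", "pre_hi", "post_class", "post_lo",
                 "post_hi", "s_con", "v_raw"],
    )


def test_class_adjustments(cfg):
    rules = _rule_frame([
        ("E", 0.12, 0.31, "SOM", 0.31, 0.77, 0.10, 0.5),
        ("E", 0.12, 0.31, "PV", 0.31, 0.77, 0.10, 0.5),
        ("E", 0.31, 0.77, "PV", 0.31, 0.77, 0.10, 0.5),
        ("E", 0.31, 0.77, "SOM", 0.31, 0.77, 0.10, 0.5),
        ("E", 0.8, 1.0, "CT", 0.8, 1.0, 1.0, 0.5),
        ("IT", 0.10, 0.29, "IT", 0.29, 0.37, 0.4, 0.5),  # L2/3 -> L4
        ("IT", 0.29, 0.37, "IT", 0.10, 0.29, 0.8, 0.5),  # L4 -> L2/3
    ])
    out = apply_class_adjustments(rules, cfg)
    assert out.loc[0, "s_con"] == pytest.approx(0.15)  # L2/3 -> SOM x1.5
    assert out.loc[1, "s_con"] == pytest.approx(0.05)  # L2/3 -> PV x0.5
    assert out.loc[2, "s_con"] == pytest.approx(0.15)  # intralaminar -> PV x1.5
    assert out.loc[3, "s_con"] == pytest.approx(0.05)  # intralaminar -> SOM x0.5
    assert out.loc[4, "s_con"] == pytest.approx(0.62)  # CT targets x0.62
    # L2/3 -> L4 rescaled to a quarter of L4 -> L2/3
    assert out.loc[5, "s_con"] == pytest.approx(out.loc[6, "s_con"] / 4.0)
    with pytest.raises(ValueError):
        apply_class_adjustments(out, cfg)  # idempotency guard


def _slab_cells(n, rng, ncd_range=(0.5, 0.75)):
    # confined to one layer so the same-layer rule keeps every pair eligible
    x = rng.uniform(-150, 150, n)
    y = rng.uniform(-150, 150, n)
    keep = x**2 + y**2 <= 150**2
    x, y = x[keep], y[keep]
    n = len(x)
    ncd = rng.uniform(*ncd_range, n)
    return pd.DataFrame({
        "cell_id": np.arange(n), "pop": "IT5B", "cell_class": "IT",
        "x": x, "y": y, "depth": ncd * 1350.0, "ncd": ncd,
    })


def test_excitatory_sampling_matches_probability(cfg):
    """Empirical connection probability within 3 binomial SD of p_con."""
    rng = np.random.default_rng(0)
    cells = _slab_cells(250, rng)
    rules = _rule_frame([("IT", 0.0, 1.0, "IT", 0.0, 1.0, 0.1, 0.5)])
    kernel = InhibKernel(border_correction=False)
    table = sample_connections(cells, rules, kernel, cfg, seed=5)
    n = len(cells)
    npair = n * n
    p = 0.1 / 0.5
    sd = np.sqrt(npair * p * (1 - p))
    # autapse removal discards ~n expected draws
    assert abs(len(table) - npair * p) <= 3 * sd + n * p


def test_inhibitory_kernel_distance_decay(cfg):
    """log(connection probability) vs distance recovers the 100-um constant."""
    rng = np.random.default_rng(1)
    cells = _slab_cells(900, rng)
    cells.loc[cells.index[: len(cells) // 3], "cell_class"] = "PV"
    rules = _rule_frame([])
    kernel = InhibKernel(base_probability=0.5, border_correction=False)
    slopes = []
    for seed in range(6):
        table = sample_connections(cells, rules, kernel, cfg, seed=seed)
        d = table["distance_um"].to_numpy()
        # bin the realized distances against candidate-pair distances
        pv_ids = cells.loc[cells["cell_class"] == "PV", "cell_id"]
        xyz = cells[["x", "y", "depth"]].to_numpy()
        from scipy.spatial.distance import cdist

        cand = cdist(xyz[pv_ids], xyz).ravel()
        bins = np.linspace(10, 250, 13)
        hit, _ = np.histogram(d, bins=bins)
        tot, _ = np.histogram(cand, bins=bins)
        p_emp = hit / np.maximum(tot, 1)
        mid = 0.5 * (bins[:-1] + bins[1:])
        ok = p_emp > 0
        slope = np.polyfit(mid[ok], np.log(p_emp[ok]), 1)[0]
        slopes.append(-1.0 / slope)
    recovered = float(np.mean(slopes))
    assert abs(recovered - 100.0) <= 15.0


def test_border_correction_equalizes_in_degree(cfg):
    """With the Monte-Carlo border correction, cells near the cylinder wall
    receive as much inhibition as central cells; without it they show a
    marked in-degree deficit."""
    rng = np.random.default_rng(5)
    cells = _slab_cells(1100, rng)
    cells.loc[cells.index[: len(cells) // 3], "cell_class"] = "PV"
    rules = _rule_frame([])
    r = np.sqrt(cells["x"] ** 2 + cells["y"] ** 2)
    wall = set(cells.loc[r >= 120.0, "cell_id"])
    center = set(cells.loc[r <= 75.0, "cell_id"])
    ratios = {}
    for corrected in (True, False):
        kernel = InhibKernel(base_probability=0.6, border_correction=corrected,
                             mc_samples=1000)
        deg_wall, deg_center = [], []
        for seed in range(8):
            table = sample_connections(cells, rules, kernel, cfg, seed=seed)
            indeg = table.groupby("post_id").size()
            deg_wall.append(indeg.reindex(list(wall), fill_value=0).mean())
            deg_center.append(indeg.reindex(list(center), fill_value=0).mean())
        ratios[corrected] = np.mean(deg_wall) / np.mean(deg_center)
    assert abs(ratios[True] - 1.0) <= 0.10
    assert ratios[False] < 0.75


def test_connection_table_properties(small_network):
    conn = small_network.connections
    assert (conn["delay_ms"] >= 2.0).all()
    assert (conn["pre_id"] != conn["post_id"]).all()
    assert not conn.duplicated(subset=["pre_id", "post_id"]).any()
    # IT -> PT exists; PT -> IT does not (unidirectional projection)
    cls = small_network.cells.set_index("cell_id")["cell_class"]
    pre_cls = conn["pre_id"].map(cls)
    post_cls = conn["post_id"].map(cls)
    assert ((pre_cls == "IT") & (post_cls == "PT")).any()
    assert not ((pre_cls == "PT") & (post_cls == "IT")).any()
    assert not ((pre_cls == "PT") & (post_cls == "CT")).any()


def test_sampling_deterministic(cfg):
    rng = np.random.default_rng(3)
    cells = _slab_cells(150, rng)
    rules = _rule_frame([("IT", 0.0, 1.0, "IT", 0.0, 1.0, 0.05, 0.5)])
    kernel = InhibKernel(border_correction=False)
    a = sample_connections(cells, rules, kernel, cfg, seed=9)
    b = sample_connections(cells, rules, kernel, cfg, seed=9)
    assert a.equals(b)
    c = sample_connections(cells, rules, kernel, cfg, seed=10)
    assert not a.equals(c)


def test_rules_csv_round_trip(tmp_path, cfg):
    from m1circuit.scenarios import fixture_strength_rules

    rules = fixture_strength_rules(cfg)
    path = tmp_path / "rules.csv"
    rules_to_csv(rules, path)
    back = rules_from_csv(path)
    pd.testing.assert_frame_equal(
        rules.reset_index(drop=True), back, check_dtype=False
    )
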