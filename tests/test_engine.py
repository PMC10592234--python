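"""Integrator verification: closed forms, conservation, determinism."""

import math

import numpy as np
import pytest

from m1circuit.engine import (
    double_exp_norm,
    double_exp_peak_time,
    simulate_single_cell,
)
from tests.conftest import passive_template


def test_passive_rc_charging_matches_closed_form():
    tpl = passive_template(n_comp=1)
    res = simulate_single_cell(tpl, duration_ms=250.0, i_inj_na=0.05, i_inj_start_ms=50.0)
    area = math.pi * 20.0 * 20.0 * 1e-8
    g_us = 5e-5 * area * 1e6
    tau_ms = 1.0 / 5e-5 * 1e-3  # cm/gl = 1 uF/cm2 / 5e-5 S/cm2 = 20 ms
    mask = res.t > 50.0
    t = res.t[mask] - 50.0
    v_inf = -70.0 + 0.05 / g_us
    analytic = v_inf + (-70.0 - v_inf) * np.exp(-t / tau_ms)
    err = np.max(np.abs(res.voltages[mask, 0] - analytic)) / abs(v_inf + 70.0)
    assert err < 0.005


def test_quiescence_without_input(it_deep_template):
    res = simulate_single_cell(it_deep_template, duration_ms=500.0)
    assert len(res.spikes) == 0
    assert np.all(np.abs(np.diff(res.voltages[-1000:, 0])) < 1e-3)


def test_determinism_bit_identical(pt_template):
    ev = [(100.0, 4, "AMPA", 0.002), (150.0, 0, "GABAA_fast", 0.003)]
    a = simulate_single_cell(pt_template, 300.0, events=ev)
    b = simulate_single_cell(pt_template, 300.0, events=ev)
    np.testing.assert_array_equal(a.voltages, b.voltages)
    np.testing.assert_array_equal(a.spikes, b.spikes)


def test_double_exponential_peak_time():
    """The conductance peak lands at the closed-form t_peak and the
    normalization yields a unit peak."""
    for tr, td in [(0.05, 5.3), (2.0, 100.0), (15.0, 150.0)]:
        tp = double_exp_peak_time(tr, td)
        t = np.linspace(0, 10 * td, 200001)
        g = double_exp_norm(tr, td) * (np.exp(-t / td) - np.exp(-t / tr))
        assert t[np.argmax(g)] == pytest.approx(tp, rel=1e-3)
        assert g.max() == pytest.approx(1.0, rel=1e-6)


def test_event_at_reversal_is_silent():
    """A GABA_A event delivered while the cell sits at -80 mV moves nothing."""
    tpl = passive_template(n_comp=2)
    res = simulate_single_cell(
        tpl, duration_ms=200.0, events=[(100.0, 1, "GABAA_fast", 0.01)], v_init=-80.0
    )
    # leak pulls toward -70; compare against the same run without the event
    ref = simulate_single_cell(tpl, duration_ms=200.0, v_init=-80.0)
    i0 = int(100.0 / 0.025)
    # at delivery time V is still ~-80 (leak tau 20 ms from -80 -> ~-73 at 100ms)
    # so use a cell clamped by strong leak to E = -80 instead:
    tpl80 = passive_template(n_comp=2)
    bio = dict(tpl80.biophysics)
    bio["e_leak_mv"] = -80.0
    import dataclasses

    tpl80 = dataclasses.replace(tpl80, biophysics=bio)
    res80 = simulate_single_cell(
        tpl80, duration_ms=200.0, events=[(100.0, 1, "GABAA_fast", 0.01)], v_init=-80.0
    )
    assert np.max(np.abs(res80.voltages[:, 0] + 80.0)) < 1e-6


def test_time_invariance_of_isolated_events():
    """Two identical events far apart evoke identical isolated EPSPs."""
    tpl = passive_template(n_comp=2)
    res = simulate_single_cell(
        tpl, duration_ms=900.0,
        events=[(300.0, 1, "AMPA", 0.002), (600.0, 1, "AMPA", 0.002)],
    )
    v = res.voltages[:, 0]
    i1, i2 = int(300 / 0.025), int(600 / 0.025)
    w = int(80 / 0.025)
    p1 = v[i1 : i1 + w].max() - v[i1 - 1]
    p2 = v[i2 : i2 + w].max() - v[i2 - 1]
    assert p1 == pytest.approx(p2, rel=1e-3)


def test_charge_bookkeeping(pt_template):
    """Per cell and time step the membrane currents sum to ~0 without
    electrode current (well-posedness of the LFP source)."""
    ev = [(float(t), c, "AMPA", 0.002) for c in (2, 4, 6)
          for t in np.arange(100.0, 400.0, 17.0)]
    ev.sort()
    res = simulate_single_cell(pt_template, 500.0, events=ev, current_stride_ms=0.5)
    sums = np.abs(res.currents.sum(axis=1))
    mags = np.abs(res.currents).sum(axis=1)
    m = mags > 0
    assert np.max(sums[m] / mags[m]) < 1e-6


def test_dt_halving_spike_stability(it_deep_template):
    """Halving dt moves spike times by less than 0.5 ms."""
    rng = np.random.default_rng(5)
    ev = [(float(t), 4, "AMPA", 0.003) for t in np.sort(rng.uniform(100, 900, 400))]
    t1 = simulate_single_cell(it_deep_template, 1000.0, dt_ms=0.025, events=ev).spikes[:, 1]
    t2 = simulate_single_cell(it_deep_template, 1000.0, dt_ms=0.0125, events=ev).spikes[:, 1]
    assert len(t1) == len(t2)
    assert len(t1) > 3
    assert np.max(np.abs(t1 - t2)) < 0.5


def test_divergence_reported():
    """A pathological cell (giant positive feedback) aborts with an error."""
    import dataclasses

    tpl = passive_template(n_comp=1)
    gbar = {k: v.copy() for k, v in tpl.gbar.items()}
    gbar["Na"][0] = 50.0  # absurd density
    gbar["leak"][0] = 0.0
    tpl = dataclasses.replace(tpl, gbar=gbar)
    bio = dict(tpl.biophysics)
    bio["e_na_mv"] = 500.0
    tpl = dataclasses.replace(tpl, biophysics=bio)
    with pytest.raises((FloatingPointError, RuntimeError)):
        simulate_single_cell(tpl, 200.0, i_inj_na=5.0, i_inj_start_ms=1.0)


def test_network_run_deterministic(small_network):
    from m1circuit.scenarios import run_scenario

    _, pooled_a = run_scenario("quiet", small_network, [0], duration_ms=1200.0,
                               warmup_ms=1000.0)
    _, pooled_b = run_scenario("quiet", small_network, [0], duration_ms=1200.0,
                               warmup_ms=1000.0)
    assert pooled_a.equals(pooled_b)
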