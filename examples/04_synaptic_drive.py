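"""Estimated synaptic drive (ESD): who drives PT5B during movement?

ESD multiplies each presynaptic cell's firing rate by the summed somatic-
uPSP weight of its contacts, then averages over the postsynaptic
population; synaptic democracy makes the mV weights location-independent,
so rate x weight is a meaningful drive estimate without recording synaptic
currents.
"""

from m1circuit.analysis import esd
from m1circuit.scenarios import (
    build_fixture_network,
    run_scenario,
    scenario_preset,
    scenario_rates,
)

net = build_fixture_network(scale=0.1, seed=1)
results, _ = run_scenario("movement", net, input_seeds=[0], duration_ms=3000.0,
                          warmup_ms=1000.0)
rates = scenario_rates(net, scenario_preset(net.config, "movement"), 0)
table = esd(net, results[0].spikes, (1000.0, 3000.0), longrange_rates=rates)

pt = table[table["post_pop"].isin(["PT5B_upper", "PT5B_lower"])]
exc = pt[pt["kind"] == "exc"].sort_values("esd_mv_hz", ascending=False)
print("strongest excitatory drives onto PT5B (mV*Hz per postsynaptic cell):")
print(exc.head(8)[["post_pop", "source", "esd_mv_hz"]].round(1).to_string(index=False))
inh = pt[pt["kind"] == "inh"]
print("\ninhibitory drive totals per PT5B subpopulation:")
print(inh.groupby("post_pop", observed=True)["esd_mv_hz"].sum().round(1).to_string())
print("\nDuring movement the motor thalamus (VL) dominates PT5B drive, with "
      "local IT input and cM1/M2 next; inhibition is reported separately.")
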