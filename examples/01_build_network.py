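"""Build the cylindrical M1 network and inspect its composition.

The cylinder is 300 um across and 1350 um deep; at full neuronal density it
holds 10,073 cells across 15 populations (16 counting the PT5B upper/lower
split).  Here we build it at 10% density, which keeps every population
populated while staying desk-sized.
"""

from m1circuit.geometry import layer_counts, layers_from_config
from m1circuit import default_config
from m1circuit.io import population_probability_matrix
from m1circuit.scenarios import build_fixture_network

cfg = default_config()
full = layer_counts(layers_from_config(cfg), 300.0, 1350.0)
print(f"full-scale cylinder: {sum(full.values())} neurons, per layer {full}")

net = build_fixture_network(scale=0.1, seed=1)
print(f"\n10% network: {net.n_cells} cells, {len(net.connections)} local "
      f"connections, {len(net.synapses)} synaptic-contact rows")
print("\ncells per population:")
print(net.cells.groupby("pop").size().to_string())

prob = population_probability_matrix(net)
print("\nconnection probability, L5B excitatory block:")
print(prob.loc[["IT5B", "PT5B"], ["IT5B", "PT5B", "PV5B", "SOM5B"]].round(3).to_string())
print("\nNote the empty PT5B->IT5B entry: the IT->PT projection is "
      "unidirectional, a defining feature of the L5 circuit.")
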