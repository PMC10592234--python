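"""Quiet wakefulness vs self-paced movement.

The quiet state drives the network with low background rates from all seven
long-range regions at medium PT I_h (75%); movement raises the motor
thalamus (VL = MTh) to 0-10 Hz and drops PT I_h to 25% (high noradrenaline).
The hallmark response is a sharp rise of PT5B corticospinal firing and a
shift of L5 LFP power from delta toward gamma.
"""

import numpy as np

from m1circuit.analysis import cell_rates
from m1circuit.lfp import Electrode, band_power, line_source_lfp
from m1circuit.scenarios import build_fixture_network, run_scenario

net = build_fixture_network(scale=0.1, seed=1)
for scen in ("quiet", "movement"):
    results, pooled = run_scenario(scen, net, input_seeds=[0], duration_ms=5000.0,
                                   warmup_ms=1000.0)
    res = results[0]
    rates = {p: cell_rates(res.spikes, net.cells_of(p), (1000.0, 5000.0)).mean()
             for p in ("IT5B", "PT5B", "PV5B")}
    currents = res.currents[res.current_t >= 1000.0]
    trace = np.mean([line_source_lfp(currents, res.comp_table, Electrode(depth=d))
                     for d in (600.0, 800.0, 1000.0)], axis=0)
    bp = band_power(trace, fs_hz=1000.0, segment_len_s=4.0)
    print(f"{scen:9s} IT5B {rates['IT5B']:5.1f} Hz  PT5B {rates['PT5B']:5.1f} Hz  "
          f"PV5B {rates['PV5B']:5.1f} Hz  "
          f"delta {bp['delta'].mean():.3f}  gamma {bp['gamma'].mean():.4f}")
print("\nPT5B rates jump from near-silence to strong movement firing while "
      "IT5B barely changes, and normalized gamma power rises severalfold. "
      "(Single-seed delta values fluctuate; the quiet > movement delta "
      "ordering emerges on averages over input seeds.)")
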