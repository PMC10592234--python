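"""Current-step characterisation of the reduced cell templates.

Each class is a few-compartment conductance-based model calibrated so its
f-I slope and rheobase match the class's target values (77 Hz/nA and
250 pA for upper-layer IT cells, 98 Hz/nA and 100 pA for deep IT, 69 Hz/nA
and 298 pA for CT).
"""

import numpy as np

from m1circuit import default_config
from m1circuit.cells import fi_curve, make_template

cfg = default_config()
for cls in ("IT2/3", "IT5B", "CT6", "PV", "SOM"):
    tpl = make_template(cls, cfg)
    slope_target, rheo_target = tpl.fi_target
    currents = np.unique(np.round(np.linspace(0.5 * rheo_target, 2 * rheo_target, 10)))
    slope, rheo, rates = fi_curve(tpl, currents)
    print(f"{cls:6s} slope {slope:6.1f} Hz/nA (target {slope_target}), "
          f"rheobase {rheo:5.0f} pA (target {rheo_target})")
print("\nSlope is the least-squares fit of rate vs current over the "
      "suprathreshold steps; rheobase the smallest current evoking a spike.")
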