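# Methods

## Scope and model summary

`m1circuit` is a desk-scale re-implementation of a multiscale circuit model
of mouse primary motor cortex (M1): a 300-um-diameter, 1350-um-deep
cylinder of cortical tissue populated by reduced conductance-based neuron
models, wired from depth-resolved connection-strength data, driven by seven
long-range input regions, and analysed through the observables used to
characterise behavioural states — line-source local field potentials (LFP),
normalized band power, estimated synaptic drive (ESD), and low-dimensional
latent dynamics.

The reference description of this circuit was developed and simulated at
full density (10,073 neurons, ~30 million synapses) on HPC resources with
morphologically detailed L5 cell models.  This package deliberately trades
that fidelity for a self-contained implementation that builds and runs on a
single CPU: few-compartment cell models, reduced network density
(configurable `scale`, default 10% in the examples and acceptance runs),
and synthetic stand-ins for data that exist only in external deposits.
Quantitative full-scale results are therefore *not* reproduced; the package
targets the construction rules exactly and the behavioural-state
phenomenology directionally.

## Geometry

Depth is expressed as normalized cortical depth (NCD): 0 at the pia, 1 at
the white matter.  Layers tile [0, 1] (L1 0–0.10, L2/3 0.10–0.29, L4
0.29–0.37, L5A 0.37–0.47, L5B 0.47–0.80, L6 0.80–1.00).  Per-layer counts
are `round(density x slab volume)`; class counts are rounded to nearest
with the residual assigned to the largest-fraction class, so totals are
conserved.  Somata are placed uniformly at random within each population's
cylindrical slab (radius via sqrt-uniform sampling).  PT cells exist only
in L5B, CT only in L6; IT:PT and IT:CT ratios are 1:1, PV:SOM is 2:1 per
layer, and the PV/SOM populations of L4 and L5A are merged into single
populations spanning both layers.  Layer densities are configuration data;
the packaged values are literature-plausible mouse neocortex numbers chosen
once so the full-density cylinder holds exactly 10,073 neurons (the
original model's configuration file is distributed in an external archive
and is not packaged).

## Cell models

Nine classes: IT2/3, IT4, IT5A, IT5B, IT6, CT6, PT5B (excitatory), PV and
SOM (interneurons).  PT5B and IT5A use 8-compartment trees (soma, axon, two
basal, trunk, nexus, two tuft); the other excitatory classes 6 compartments
and the interneurons 3 (soma, axon, dendrite).  Channels are standard
Hodgkin–Huxley formulations shared across classes — Na (m^3 h), Kdr (n),
Ka (a·b), Kd (slow, c·d), HCN (q), CaL/CaN (m^2) and a saturating
Ca-dependent K conductance fed by a single-pool Ca ladder — with class
identity carried by the morphology and per-compartment conductance
densities.  The apical tree of each excitatory template is rescaled so the
soma-to-pia extent matches its layer's mean depth, which introduces small
systematic excitability differences across layers.

Templates share parameter sets: the upper-IT set serves IT2/3 and IT4 (and
the same channel densities underlie CT6, with its own calibration), the
deep-IT set serves IT5A/IT5B/IT6.  Each template carries two calibration
scales — `leak_scale` (input resistance, controls rheobase) and
`adapt_scale` (Ca-dependent K, controls f-I slope) — tuned by alternating
proportional updates under a fixed protocol (ten 1-s current steps spanning
[0.5, 2] x target rheobase; rheobase = smallest current evoking a spike;
slope = least-squares rate-vs-current fit over suprathreshold steps).
Calibration targets: upper IT 77 Hz/nA and 250 pA, deep IT 98 Hz/nA and
100 pA, CT 69 Hz/nA and 298 pA; all verified within ±15%.  The PT and
interneuron targets are package choices frozen from the calibrated
deterministic measurement: PV is a type-II (discontinuous-onset) firer
whose fitted slope is protocol-sensitive (755 Hz/nA, 100 pA), SOM is
low-threshold (457 Hz/nA, 35 pA), and the PT baseline is discussed below.

### HCN, the I_h shunt, and noradrenergic modulation

PT5B carries the dominant HCN conductance (apical-weighted, with a CaL/CaN
"hot zone" between nexus and tuft).  The noradrenaline (NA) proxy is
`ih_fraction`: 1.0 at the in vitro baseline (no NA), 0.75 in quiet
wakefulness, 0.25 during movement.  `k_scale` multiplies the voltage-gated
K conductances of all excitatory classes (1.5 in the modified NA-R-block
condition).

HCN is paired with a *static shunt leak* proportional to the local HCN
conductance density (gain 0.85, reversal −90 mV), scaled by `ih_fraction`
together with HCN itself.  The design rationale: near rest the activated
I_h (reversal −30 mV) depolarizes, so weak inputs are facilitated; under
strong synaptic drive the gate deactivates while the shunt persists, so
strong I_h turns net inhibitory — the excitation-to-inhibition switch.  A
shunt proportional to the *instantaneous* activation cannot produce this
switch (it deactivates together with I_h), which is why the static form was
chosen.  The same mechanism produces the network-level signature used in
model tuning: PT5B rates increase as `ih_fraction` drops from 1.0 to 0.25.

A consequence accepted deliberately: at the in vitro baseline (ih = 1.0)
the shunt plus saturating adaptation clamp sustained PT firing above
~1 nA, so the protocol's fitted f-I slope is small (2.63 Hz/nA) with a
high rheobase (650 pA).  In its network operating regime (ih ≤ 0.75,
fluctuating synaptic drive) the cell fires normally.

## Wiring

Excitatory connection strength s_con (mV) is the product of connection
probability p_con and unitary somatic EPSP v_con: v_con comes from a
layerwise unitary-EPSP matrix interpolated piecewise-linearly onto NCD band
midpoints and clipped to [0.3, 1.0] mV; p_con = s_con / v_con, clipped to 1
(clipping logged).  The packaged depth-resolved strength table is a
synthetic fixture (the measured matrices live in the external deposit)
that encodes the qualitative circuit: strong L2/3 -> upper L5B PT,
unidirectional IT -> PT, recurrent intralaminar excitation, an L6 IT/CT
loop, and feedforward L4 -> L2/3 four times stronger than its reciprocal.
Class-specific adjustments are applied programmatically: L2/3 -> SOM of
L4/5A/5B x1.5 and -> PV x0.5, the opposite pattern for intralaminar L4/5
inputs, CT-target strengths x0.62, and the L2/3 -> L4 rescaling to a
quarter of L4 -> L2/3.

Interneuron outputs are confined to the (merged) layer of the presynaptic
cell with probability p0·exp(−d/100 um) in 3-D intersomatic distance
(p0 = 0.25 configured).  A Monte-Carlo border correction (1000 samples per
cell from the 2-D kernel) boosts each postsynaptic cell's p0 by the inverse
of the kernel mass retained inside the cylinder, removing the in-degree
deficit at the wall.  Delays are 2 ms plus distance at 0.5 m/s.  Unitary
IPSP amplitudes (PV 0.9 mV, SOM 0.3 mV) are package choices — the source
prints only receptor kinetics.

## Synapses

Weights are somatic-uPSP equivalents (mV) converted to conductances through
*synaptic democracy*: for each template compartment a bisection finds the
AMPA conductance evoking a 0.5 mV somatic EPSP (200 ms settling, 50 ms peak
window, 1% tolerance); the compartment's scale factor is that conductance
normalized to the somatic one, capped at 4.0 so distal tuft synapses do not
overexcite the network.  Unitary connections onto the detailed templates
(PT5B, IT5A) are distributed over 5 contacts, others over 1; per-contact
weight is v_con/n_syn.

Excitatory synapses carry colocalized AMPA (0.05/5.3 ms) and NMDA
(15/150 ms), each at 50% of the weight, NMDA under the Mg block
1/(1 + 0.28·Mg·exp(−0.062 V)) with Mg = 1 mM.  PV outputs use fast GABA_A
(0.07/18.2 ms, −80 mV) placed within 50 um of the soma on excitatory
targets; SOM outputs target apical dendrites with slow GABA_A (2/100 ms)
and, onto excitatory cells, 10% GABA_B by weight.  GABA_B is approximated
as a slow double-exponential conductance (50/300 ms, −95 mV) standing in
for the second-messenger GIRK pathway; the full kinetic scheme is an
extension point.  All inputs onto interneurons land on the dendrite.
Contacts follow projection-specific radial density profiles (sCRACM-style:
map amplitude / dendritic length, averaged across the horizontal axis,
normalized) where defined — VL and cM1/M2 onto PT, local IT onto PT — and a
dendritic-length-weighted uniform distribution otherwise.

## Long-range drive

Seven regions (PO, VL≡MTh, S1, S2, cM1, M2, OC), each 1000 independent
Poisson units with per-unit rates drawn uniformly from a state-dependent
range; all long-range unitary weights are 0.5 mV.  The per-cell contact
budget derives from 8234 average contacts: 80% excitatory of which 80%
long-range (5270), 20% inhibitory of which 30% long-range (494, carried by
a generic inhibitory source with fast GABA_A kinetics).  Convergence per
(region, class) is the excitatory budget x region share x normalized input
strength; shares and strengths are fixture data following the qualitative
projection pattern (PO/S1/S2 -> superficial IT, VL -> PT and L4 IT, cM1/M2
-> deep IT/PT, OC -> L6).  Spontaneous ranges are 0–2.5 Hz for the cortical
regions and PO and 0–5 Hz for VL (the sources state "0–2.5 or 0–5 Hz"
without a per-region assignment); "increased" drive is 0–10 Hz.  At reduced
network scale the convergences are scaled by 0.6 and global weight scales
(E→E 0.65, E→I 2.0, I→X 2.5) restore the excitation/inhibition balance that
full density provides naturally — the counterpart of the original model's
iterative grid-search tuning, judged by the same two criteria
(physiological rates per class; PT5B rates increasing from high to low I_h).

## Engine

Per time step (dt = 0.025 ms default): channel gates advance by exponential
Euler on voltage-indexed lookup tables; the voltage solve is a theta-method
(theta = 0.5, Crank–Nicolson-like) implicit step of the cable equation on
each cell's tree via Hines elimination (parents ordered before children).
Synaptic receptors are aggregated double-exponential conductances per
(receptor, compartment), normalized so a unit weight yields a unit peak;
events travel through a per-step delay ring buffer (delays quantized to the
grid; the 2 ms floor is 80 steps).  Spikes are positive-going 0 mV
crossings at the soma with a 2 ms refractory.  Membrane currents for the
LFP are the per-compartment net axial currents (plus any electrode
current), which sum to zero per cell by construction.  Identical inputs
give bit-identical outputs; random streams are named substreams (geometry,
wiring, placement, long-range, rates, trains) of the two seed roles
(connectivity, input).

Verification: passive RC charging matches the closed form to <0.1%;
dt-halving moves spike times of a 50-cell recurrent fixture by <0.5 ms;
per-cell current sums are <1e-6 of the absolute current magnitude.

## LFP and band power

The extracellular potential is the line-source sum over compartment
segments in a homogeneous medium (sigma = 0.3 mS/mm), using the stable
asinh form of the line integral, which reduces to 1/(4·pi·sigma·r) in the
point limit (verified to <1%); electrodes closer than 1 um to a segment are
clamped with a warning.  Per-population LFPs restrict the same transfer
coefficients to one population's compartments, so the decomposition is
exactly additive.  The L5 statistic averages electrodes at 600, 800 and
1000 um.

Band power follows the experimental pipeline: 4-s segments, complex Morlet
wavelet PSD (omega = 6; pywt `cmor2.0-0.9549`), min–max normalization of
the PSD within each segment over a 60-point log grid from 1 to 100 Hz, and
band means for delta (0–4 Hz), theta (4–8), alpha (8–12), beta (12–30) and
gamma (30–80).  Each segment is linearly detrended before the transform: a
4-s window holds under one cycle at 1 Hz, so residual drift in the
simulated currents would otherwise appear as a spurious dominant delta peak
under min–max normalization.  Total-power normalization is implemented as
an alternative (`normalization="total"`); min–max is the default and the
choice is recorded in the output metadata.

## Analysis

Rates exclude a 1-s warm-up; the >0 Hz filter is an explicit flag used only
where a comparison requires it.  ESD is S = (1/N_post) sum_i sum_j r_j w_ij
with w in mV (somatic-uPSP weights, meaningful because of synaptic
democracy); excitatory and inhibitory sources are reported as separate
positive-magnitude rows, and long-range inhibition is included in totals.
Enhanced/suppressed classification uses a 0.1 Hz rate-change threshold
(configurable).  Latent dynamics: UMAP to 3-D of binned rates (25-ms bins
for 1000 sampled cells, 10-ms bins for the 16 populations), silhouette on
state labels, reconstruction via the UMAP inverse transform (Pearson r),
cubic smoothing splines for display.  Statistical comparisons use the
two-sided Wilcoxon rank-sum test with Bonferroni correction, with an exact
Mann–Whitney fallback for fully tied samples.

## Synthetic observables and what passing tests show

`generate_synthetic_observables` emulates spikes (sinusoidally modulated
Poisson), per-compartment currents and composite LFP traces with prescribed
rates, oscillation frequencies and amplitudes, so the observable code is
testable without the simulator.  It does not emulate cell-type-specific
current waveforms, electrode geometry, or cross-population correlations;
tests passing on it validate the *math* of the observables, not the realism
of the simulated signals.

## Problem sizes

Default analysis sizes (package choices): 10% neuronal density (~1000
cells), behavioural states simulated for 5 s (1 s warm-up + one 4-s
analysis window) over 2–3 input seeds, a 3-point NA axis at maximal MTh
drive instead of the full 5x5 MTh x NA grid, and 10 connectivity seeds for
the inhibitory-kernel recovery.  The directional results reported by the
acceptance script were verified to hold at these sizes.

## Known limitations

- Reduced morphologies cannot reproduce dendritic spike phenomenology; the
  HCN shunt is the only dendritic nonlinearity retained by design.
- The packaged connectivity matrices, long-range shares/strengths and layer
  densities are synthetic stand-ins for deposited datasets; analyses that
  require the deposits (exact paired-segment counts, outlier-cluster
  fractions) run only when those files are supplied under `data/external/`.
- Band-power directions (delta down, gamma up in movement) are emergent
  stochastic properties of a ~1000-cell network and hold on seed averages,
  not necessarily per seed.
- No synaptic plasticity, no within-population parameter diversity, no
  time-varying long-range rate profiles; GABA_B omits the second-messenger
  cascade; membrane-voltage trajectories are not fitted.
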