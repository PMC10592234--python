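# m1circuit

A desk-scale model of the mouse primary motor cortex (M1) microcircuit:
data-driven network construction, reduced conductance-based dynamics,
behavioural-state presets, and the observables used to characterise cortical
states — local field potentials, band power, estimated synaptic drive, and
latent population dynamics.

## The scientific problem

Motor cortex output is carried by layer 5B pyramidal-tract (PT,
corticospinal) neurons, which sit in a circuit with highly specific wiring:
intratelencephalic (IT) cells project onto PT cells but not the reverse,
the strength of L2/3 input depends on a PT cell's depth within L5B, and
inhibition from PV (perisomatic) and SOM (dendrite-targeting) interneurons
is layer-organized.  Behavioural state reaches this circuit through two
channels: motor thalamus (MTh/VL) firing, which rises during movement, and
noradrenaline, which suppresses the HCN current I_h of PT cells.  The model
asks how these two inputs gate the IT- vs PT-dominated output modes of M1,
and what signatures they leave in firing rates and the L5 LFP.

The package builds a cylindrical patch of M1 (300 um diameter, 1350 um
depth; 10,073 neurons at full density, a configurable fraction at desk
scale) in a normalized-cortical-depth (NCD) coordinate system, with:

- connection strength s_con = p_con x v_con decomposed from depth-resolved
  strength matrices, v_con clipped to [0.3, 1] mV;
- *synaptic democracy*: per-compartment weight scaling (capped at 4.0) so a
  unitary connection's somatic EPSP is independent of dendritic location;
- exponential distance-dependent inhibition (length constant 100 um) with a
  Monte-Carlo border correction;
- seven long-range Poisson input regions with convergences budgeted from
  8234 synaptic contacts per cell (80% excitatory, of which 80% long-range);
- an implicit (Crank–Nicolson / Hines) compartmental integrator with
  event-driven AMPA/NMDA/GABA_A/GABA_B synapses and an NMDA Mg2+ block;
- line-source LFP with exact per-population decomposition, Morlet-wavelet
  band power in the five canonical bands;
- estimated synaptic drive, S = (1/N_post) * sum_ij r_j w_ij (rate x
  somatic-uPSP weight summed over contacts, averaged over the postsynaptic
  population);
- UMAP latent dynamics with silhouette and inverse-transform reconstruction.

See `docs/methods.md` for the model assumptions, parameters and
limitations.

## Worked example

```bash
python examples/03_quiet_vs_movement.py
```

builds the 10%-density network (seed 1) and simulates 5 s of quiet
wakefulness and 5 s of movement (input seed 0), printing:

```
quiet     IT5B   2.7 Hz  PT5B   0.0 Hz  PV5B   0.0 Hz  delta 0.435  gamma 0.0038
movement  IT5B   2.8 Hz  PT5B  19.1 Hz  PV5B  22.2 Hz  delta 0.486  gamma 0.0184
```

Quiet wakefulness drives all seven long-range regions at background rates
(<= 5 Hz) with PT I_h at 75%; movement raises motor-thalamus drive to
0–10 Hz and drops PT I_h to 25%.  PT5B cells switch from near-silence to
strong firing while IT5B barely moves — the PT-dominated output mode — and
the L5 LFP gamma band (30–80 Hz) gains normalized power.  (Band powers are
per-segment min–max-normalized Morlet PSDs averaged within each band;
single-seed delta values fluctuate, and the quiet > movement delta ordering
holds on seed averages.)

The other examples cover network construction and the connection
probability matrix (`01`), f-I calibration of the cell classes (`02`),
estimated synaptic drive onto PT5B (`04`), and latent dynamics (`05`).

A thin command-line interface wraps the same pipeline:

```bash
m1circuit build --scale 0.1 --seed 1 --out out/
m1circuit simulate --scenario movement --seed-grid 0,1 --out out/
m1circuit report
```

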