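# astrofilter

Simulation and analysis toolkit for **glutamate-mediated astrocytic filtering
of neuronal activity** in mixed neuron–astrocyte cultures.

Astrocytes respond to synaptically released glutamate with intracellular
Ca²⁺ transients, but they are not a passive readout: their Ca²⁺ response is a
strongly nonlinear function of the neuronal firing rate, with a sharp *onset
frequency* (a few Hz) below which they ignore neuronal activity. This package
implements the computational side of that study: it builds synthetic cultures
with realistic spatial statistics, infers gap-junction (GJC) coupling between
astrocytes from a Voronoi tessellation of the cell field, drives a
biophysical astrocyte model with stimulation pulse trains, and quantifies the
simulated Ca²⁺ traces exactly as one would the imaging data — responsiveness,
logistic/exact onset frequencies, response delays, and Morlet-wavelet
oscillation spectra (Type I vs Type II responses).

## The model

Each astrocyte is a three-variable **G-ChI** unit — cytosolic Ca²⁺ `C`,
available IP₃-receptor fraction `h`, and cytosolic IP₃ `I` — combining
IP₃-receptor-mediated calcium-induced calcium release (CICR) with IP₃
metabolism:

```
dC/dt = J_C + J_L − J_P
dh/dt = Ω₂ [ Q₂ (1 − h) − C h ],     Q₂ = d₂ (I + d₁)/(I + d₃)
dI/dt = a·J_β(G) + J_δ − J_3K − J_5P + Σⱼ J_ij
```

where `J_C` (IP₃R channel), `J_L` (ER leak) and `J_P` (SERCA pump) govern
CICR; `J_β` is glutamate-driven PLCβ production (only in directly stimulated
cells, `a = 1`), `J_δ` Ca²⁺-activated PLCδ production, and `J_3K`, `J_5P`
enzymatic degradation. Coupled astrocytes exchange IP₃ through a sigmoidal,
gradient-thresholded GJC flux

```
J_ij = sign(ΔI) · (F/2) [ tanh((|ΔI| − I_θ)/ω_I) + tanh(I_θ/ω_I) ]
```

Stimulation enters through a Tsodyks–Markram *equivalent synapse* (lumping
all synapses enwrapped by one astrocyte): facilitation `u` and depression `x`
set the released fraction `r = u⁺x⁻` per pulse, each release adds glutamate
that is cleared exponentially. The synapse is solved exactly event-by-event;
the network ODEs are integrated with a stiff-capable adaptive solver (a
numba-compiled right-hand side, with a NumPy reference implementation
cross-checked in the tests).

All kinetic constants live in one audited JSON file
(`src/astrofilter/data/parameters.json`, µM/seconds, schema-validated); the
model refuses to run without an explicit parameter file.

## Worked example

`examples/01_single_astrocyte_onset.py` sweeps an isolated astrocyte through
30 s pulse trains between 0.5 and 10 Hz:

```
resting state: Ca = 0.028 uM, IP3 = 0.009 uM, h = 0.84

stimulation frequency (Hz) -> responsiveness (AU):
   0.50   0.092
   1.18   0.397
   1.86   1.468
   2.54   2.160
   ...
  10.00   5.333

exact onset frequency: 1.86 Hz
```

Below ~1.9 Hz the cell's IP₃ settles at a sub-threshold plateau and the
responsiveness (mean stimulated ΔF/F₀ minus spontaneous, in arbitrary units)
stays small; above it, IP₃ crosses the CICR threshold and large Ca²⁺ spikes
appear — the curve inflects, which is how the *exact onset frequency* is
located. The other examples cover culture/network generation (degree
statistics with ~1/5 isolated astrocytes), coupling effects on timing and
oscillation spectra, and the full population pipeline with the predicted
negative correlation between single-cell onset and oscillation frequency.

A thin CLI wraps the pipeline:

```bash
astrofilter run --seed 1 --outdir out/       # generate → simulate → analyze
astrofilter generate --seed 1 --outdir out/  # individual stages
astrofilter build-net --culture out/culture.csv --outdir out/
```

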