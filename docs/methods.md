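# Methods

## Scope and design

`astrofilter` models how astrocytes in mixed neuron–astrocyte cultures filter
neuronal activity by its frequency. The pipeline mirrors an MEA +
Ca²⁺-imaging experiment one-to-one: a 2D cell field (here synthetic), a
gap-junction network inferred from cell positions, electrical pulse trains
delivered to the stimulated astrocytes through glutamatergic synapses, and
the same trace analyses one would run on imaging data. Cells are treated as
perfectly stirred points: no subcellular Ca²⁺ microdomains, no spatial IP₃
gradients within a cell, and no Ca²⁺ exchange through gap junctions (only
IP₃ diffuses between cells).

## Synthetic cultures

Cell somata are placed by a hard-core point process: the target count is
Poisson(density × area) and positions are drawn by sequential rejection with
a minimum inter-soma distance (default 10 µm, a typical soma scale). An
explicit `PackingError` is raised when the radius cannot be packed at the
requested density. Classes (astrocyte / neuron / unclassified) and
stimulated flags are i.i.d. per cell; only astrocytes can be stimulated.

Defaults: 500 × 500 µm field (order of an imaged field at ×20), 800
cells/mm² (an imaged-field constant, deliberately below plating density:
only cells with usable Ca²⁺ signals enter the analysis), class fractions
astrocyte : neuron : unclassified = 0.25 : 0.45 : 0.30, stimulated fraction
0.5. The astrocyte fraction is the one structural knob that controls the
astrocyte–astrocyte Voronoi degree distribution (for a thinned homogeneous
process the distribution is density-invariant), and 0.25 was chosen
analytically — E[(1−p)^D] with mean Voronoi degree 6 — so that roughly a
fifth of astrocytes are isolated and a third have exactly one neighbour,
with occasional clusters of ≥5; the unit tests verify these ensemble
statistics. "Unclassified" doubles for unresponsive astrocytes, which are
excluded from network building exactly like neurons. Spatial clustering of
stimulated astrocytes is not modelled (responsive astrocytes are distributed
uniformly around the stimulating electrode).

What the generator does **not** emulate: fluorescence noise, imaging
artifacts, cell-shape anisotropy, and any correlation between class and
position. Passing tests therefore say nothing about segmentation or
baseline-estimation robustness on real images.

## Network inference

All cells enter a Voronoi tessellation; two astrocytes are coupled iff their
regions share a border of positive length, so an interposed neuron or
unclassified cell separates them. Unbounded border regions are clipped to
the field rectangle before adjacency is computed (finite images; infinite
regions would create spurious far-field adjacencies), and degenerate point
contacts (cocircular sites) are not edges. Fewer than three non-collinear
cells fall back to a 1D nearest-neighbour rule with a warning. The
implementation is validated against a brute-force perpendicular-bisector
oracle on random instances.

## Astrocyte dynamics

The three-variable G-ChI unit (C, h, I) follows the standard formulation:
Li–Rinzel CICR gating (`m∞ = I/(I+d₁)`, `n∞ = C/(C+d₅)`, flux
`r_C (m∞n∞h)³ (C_T − (1+ρ_ER)C)`), linear ER leak, Hill-2 SERCA pump;
glutamate-driven PLCβ with Hill exponent 0.7 and Ca²⁺(PKC)-shifted affinity;
Ca²⁺-activated, IP₃-inhibited PLCδ; Hill-4 Ca²⁺-dependent IP₃-3K and linear
IP-5P degradation. Parameters are in the frequency-modulation (FM) encoding
regime: above onset, stronger drive raises the oscillation frequency with
little amplitude change.

The GJC flux is a sigmoid of the absolute IP₃ gradient, directed
down-gradient, with threshold `I_θ = 0.15` µM, stiffness `ω_I = 0.05` µM and
strength `F = 3` µM/s. The raw `sign(ΔI)`-gated sigmoid is discontinuous at
ΔI = 0 by its tail value, which stalls adaptive solvers once coupled cells
synchronise; the implementation subtracts the tail so the flux is exactly
zero and continuous at zero gradient (< 0.5% of F anywhere for
`I_θ ≥ 3 ω_I`; the F/2-at-threshold identity holds to the same accuracy).

## Synaptic drive

Each stimulated astrocyte receives one equivalent synapse (all synapses it
enwraps, lumped). Facilitation `u` (decay Ω_f, increment `u₀(1−u)` per
pulse, facilitation applied before release) and resources `x` (recovery Ω_d,
consumed by `r = u⁺x⁻`) follow the Tsodyks–Markram model with pulses treated
as exact impulses; between pulses all synaptic variables have closed-form
solutions, so the whole release sequence is computed event-by-event with no
time-step error and enters the ODE right-hand side as an analytic
piecewise-exponential glutamate forcing (clearance rate Ω_c). The solver's
maximum step is bounded below the inter-pulse interval inside trains.

## Parameter calibration

The kinetic constants (one JSON file, µM and seconds, schema-validated)
start from the published FM-regime G-ChI values and were calibrated — as the
study design prescribes — against four stated model behaviours: (i) the
maximal Ca²⁺ oscillation frequency of a strongly driven astrocyte is
~0.2 Hz (a uniform kinetic scaling plus a slower IP₃R inactivation rate);
(ii) the single-cell onset of responsiveness sits near 2 Hz (glutamate
release scale); (iii) a directly stimulated astrocyte initiates its response
within ~1.5 s at the highest stimulation frequencies (PLCβ maximal rate and
short-term-depression recovery, which set the high-frequency drive);
(iv) PLCδ production is low enough that an oscillating astrocyte's
unstimulated neighbour shows only sub-threshold IP₃/Ca²⁺ elevations (no
regenerative intercellular waves), and the doubly-coupled cell's oscillation
plateau falls in the 0.08–0.14 Hz band (GJC strength). The SERCA affinity
was lowered (K_ER = 0.05 µM) to put the cell in a relaxation-spike regime:
low sub-threshold Ca²⁺, ~1 µM spikes, and a strongly frequency-modulated
cycle — the regime in which the responsiveness curve shows a sharp
inflection at the onset.

Two behaviours of the reference study are **not** reproduced by this
parameter set, and the corresponding checks are deliberately left failing:
the onset shift with coupling degree saturates near 3.6 Hz (k = 1) and
4.4 Hz (k = 2) instead of ~5 and > 10 Hz, and the gap-junction transmission
delay is either ~0.4 s (neighbour recruited within the same IP₃ surge, at
strong coupling) or one full oscillation period (~4.4 s), never the
intermediate ~2 s. Both are structural consequences of this model family as
calibrated here: the drive a coupled cluster shares grows as
`(f·r(f))^0.7`, so with depression slow enough to satisfy the 1.5 s timing
criterion the mid-band drive rises too steeply to postpone the k = 2
crossing much beyond 6 Hz, and neighbour recruitment is quantised by the hub
oscillation cycle.

## Trace analysis conventions

* Simulated Ca²⁺ is mapped to the imaging observable as
  `ΔF/F₀ ≈ (C − C_rest)/C_rest`.
* **Responsiveness** r: mean of the normalized trace over stimulation
  windows minus the mean over a spontaneous window (per-unit-time sums at
  uniform sampling reduce to window means); dimensionless (AU).
* **Onset frequency** (sparse sweeps): four-parameter logistic fit
  `R(f) = A + (B−A)/(1+exp(−(f−C)/τ))` with B ≥ A, τ > 0 and the midpoint
  constrained non-negative; onset is the 10%-of-maximum point
  `C − τ ln 9`, with a 95% CI from the fit covariance. If the curve never
  plateaus the rising limb is fitted exponentially and flagged. Per-cell
  fits on sparse sweeps can extrapolate an onset below the sweep (the cell
  responds at all tested frequencies); rank statistics over cells are the
  interpreted quantity.
* **Exact onset** (dense model sweeps): the frequency of the peak of the
  normalized numerical derivative (dR/df)/max(dR/df); flagged when the
  derivative is flat. Sweeps use ~15 linearly spaced frequencies and 30 s
  trains, mirroring the stimulation protocol.
* **Response delay**: first time after stimulation start at which the
  normalized trace exceeds 60% of its maximum over the analysis span
  (responses below 0.3 ΔF/F₀ don't count); delay < 1.5 s classifies a cell
  as directly stimulated.
* **Spectra**: Morlet CWT (center frequency 0.8125) on 64 log-spaced scales
  covering 0.07–0.5 Hz; the plane is restricted to in-stimulation time
  points carrying a coefficient ≥ 70% of the cell's largest (magnitude, not
  power), frequencies below 0.07 Hz are cut (removes the 1/30 s protocol
  line), the per-time argmax gives representative frequencies (ties toward
  the lower frequency), and the cell is summarised by their mean and 95th
  percentile ("maximal oscillating frequency"). The 70% threshold is
  per-cell. Oscillation-frequency sweeps use 90 s trains and exclude points
  where the cell fires fewer than 3 transients or at a rate below the
  0.07 Hz band floor — rhythms slower than the analysis band cannot be
  measured, and the argmax would otherwise reflect single-transient width.
* **Type I/II**: a two-component Gaussian mixture on the maximal-frequency
  histogram labels cells by posterior (low mode = Type I), falling back to
  one component (all unlabeled) when BIC, weights or separation do not
  support bimodality.

## Numerics

LSODA with rtol 1e-6 / atol 1e-9, output step 0.1 s (≥ 10 samples per
fastest oscillation; delays are measured on a 0.02 s grid where stated);
integration is chunked at protocol-segment boundaries; state bounds
(C, I ≥ 0, 0 ≤ h ≤ 1) are asserted on every simulation; halving tolerances
changes Ca²⁺ traces by < 1% (tested). The resting state is found by
integrating an isolated unstimulated cell to |dy/dt| < 1e-9 µM/s and
polishing with a root solve; a non-convergent rest is reported as a
parameter-regime error. The compiled (numba) right-hand side is asserted
equal to the NumPy reference in the tests.

## Problem sizes

Default analysis runs use 15-frequency sweeps with 30 s trains and 30 s
spontaneous windows; oscillation spectra use 90 s trains; population studies
use three 500 × 500 µm cultures (~70 stimulated astrocytes) with a
7-frequency sweep and a 10 Hz spectral run. All results in the acceptance
report regenerate in a few minutes on one CPU.

## Known limitations

Somatic signals only; deterministic IP₃R gating; one shared kinetic set for
all astrocytes (heterogeneity enters through topology only); identical
equivalent synapses for all stimulated cells; no fluorescence/imaging noise,
so absolute responsiveness values (AU) are on the model's own scale; the
onset-shift and transmission-delay mismatches described under calibration.
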