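# Methods

## Model and assumptions

The simulator treats the locomotor cerebellar network as a feed-forward chain
of *code groups*: topographically defined cell populations whose
instantaneous output frequency distribution is the information carrier.
Every computational node (a Golgi dendrite, a glomerulus, a granule cell, a
stellate cell, a Purkinje dendritic compartment, a DCN soma) performs a
linear function — a mean — of a random sample of the afferent group's
output.  Anatomy is assumed to *simulate* independent random sampling with
replacement, so the central limit theorem governs every conversion: each
stage's output distribution is narrower than its input, approximately
normal, and linearly coupled to the input mean.  The simulation takes that
premise literally: sampling is implemented as genuine i.i.d. draws, and no
biophysics (membrane time constants, conductances, spike generation except
in the DCN raster module) is modelled.

Rates are carried on a normalized scale: the affine image of the mossy-fiber
physiological range (50–300 Hz by default) onto [0, 1], clamped so that
rates outside the scale saturate rather than carry negative drive.  The
absolute calibration of each stage is deliberately not a model target — only
the sign, linearity and narrowing of each coupling matter — so normalized
values at inner stages are not predictions of firing rates in Hz.

Snapshots, not dynamics: one simulation run represents one instant of
behaviour.  Temporal structure appears only in the two modules where it is
the point (the millisecond-binned Purkinje→DCN rasters, and the STP
derivative model).

## Anatomical parameters

All constants live in `NetworkConfig` (units in field names; literature
mid-range defaults).  The load-bearing ones:

| parameter | default | role |
|---|---|---|
| `n_microstrips` | 41 | afferent strips (20 per side + the strip beneath); nominal 40 used for field bookkeeping |
| `fields_per_microstrip` | 100 | 200 µm sagittal fields tiling the 20,000 µm microzone |
| `terminals_per_field` | 700 | glomeruli per field; primary constant (not derived) |
| `terminals_per_cluster_mean` | 7.5 | copies added per sampled rate (drawn from {7, 8}) |
| `mf_per_field` / `branches_per_mf_per_microstrip` | 180 / 4.5 | fix the strip fiber count at ~4,000 and the 97% duplication cost |
| `golgi_per_field`, dendrites × sample | 10, 5 × 4 | Golgi step-1 sampling (20 terminals/cell) |
| `glomerulus_golgi_sample` | 8–12 | step-2 ensemble sampling per glomerulus |
| `granule_per_field`, `granule_dendrites`, `min_dominant_inputs` | 8,750, 4, 3 | activation rule |
| `stellate_pf_contacts` | 1,000 | Binomial n for active stellate inputs |
| `stellate_per_pc_inner` | 16 | 8 afferents per side of each Purkinje cell |
| `compartment_stellate_sample` | 8–12 | per-compartment sampling |
| `inversion_r0/ke/ki` | 1.0 / 0.5 / 1.5 | excitation/inhibition inversion (unit net slope −1) |
| `pc_per_dcn` | 30–50 (mean 45) | DCN convergence |
| `silent_synapse_fraction` | 0.825 | enters only as a multiplicative working-contact factor (learning is out of scope) |

The arithmetic linking 180 fibers, 7.5 terminals/cluster and 700 glomeruli
per field is over-determined (180 × 7.5 ≠ 700); 700 is taken as primary and
the cluster count per field is 700/7.5 ≈ 93, drawn from the field's
180-fiber sample.

## Design choices where the design was open

**Neutral gain and the ~30% regime.**  With 4 dendrites and a 3-dominant
threshold, a per-dendrite dominance probability of ½ gives an active
fraction of P(Binom(4, ½) ≥ 3) = 0.3125.  Since the glomerular inhibition is
an unbiased estimate of the mossy mean, gain = 1 puts the dominance
threshold at the input median — so the ~30% regime is the *neutral* point of
the regulation, and there the active fraction is exactly shape-invariant for
symmetric input distributions.  Away from it (multiplicative gain ≠ 1) the
threshold sits in the distribution tail and strict shape invariance cannot
hold for a threshold rule; the shape-invariance analyses are therefore run
at the neutral point, while sparse codes (1%, gain ≈ 1.7) are used where
sparseness itself is the subject.

**Strip ends.**  The 3-field Golgi ensemble window truncates to 2 fields at
fields 1 and 100; clusters at strip ends spill inward only.

**Boundary straddling.**  Each cluster spills a uniform-random 0–30% of its
copies into one adjacent field (`straddle_max_fraction`); the fraction is
not reported anywhere, so it is exposed in the config.

**Compartment pools.**  A compartment samples (with replacement, size 8–12)
from the PC's 8 same-side afferent stellate cells *plus* the matching 8 of
the sagittally adjacent sector, reflecting the sagittal reach of the
stellate main axon; the soma therefore effectively averages ~32 distinct
cells, giving the observed ~5× narrowing from stellate to soma.

**Stellate spontaneous floor.**  Cells with zero active inputs emit the
normalized value 0.1 (spontaneous firing modulated by input; the value is
unreported and configurable).  At very sparse codes these floor cells are
rare but far from the active-rate mean, so they can dominate the stellate
SD; the SD-ordering property (PC < stellate < parallel fiber) is a CLT
statement about the sampling chain and is checked at codes where floor cells
are absent.

**Stellate input counts in the microzone-synchrony pipeline.**  The
canonical microzone experiment (`fig6`) illustrates the granule rate data at
the dense ~30% regime while drawing stellate active-input counts from the
sparse regulated proportion (0.5%, mean ~5 inputs per cell).  Both numbers
are anatomical set points of the model, and the combination is what the
inhibition-synchrony demonstration requires: a visible stellate spread
(single-figure samples) recoded into tightly grouped Purkinje somata.
`molecular_layer(..., input_fraction=...)` exposes the override; by default
counts follow the code's own active fraction.

**Distal parallel-fiber taper.**  Parallel fibers make about half as many
synapses distally as proximally; `distal_strip_weights` implements the
linear 1.0 → 0.5 taper and the aggregation and sampling machinery accepts
per-strip weights throughout.  The taper governs the *mutual influence of
neighboring networks*, and is not applied inside the default within-network
readout: a triangular weight window whose width equals one body wavelength
passes ~12% of the wave's fundamental, which would make a full body wave
partially readable — the opposite of what the readout does (the full-wave
readability index measures 0.116 with the taper vs 0.022 without).

**DCN inversion.**  DCN output is the normalized complement `1 − mean` of
the sampled Purkinje somata, not a pacemaker model; spontaneous 70–110 Hz
firing is out of scope.  The double inversion (parallel fiber → PC, PC →
DCN) makes motor output track input drive positively.

**Swimming operating point.**  The swim pipeline defaults to the ~30%
(neutral-gain) granule regime.  At a 1% target the calibrated multiplicative
gain (~1.2 for the swim input spread) makes the per-strip active fraction
vary ~40-fold across a quarter-wave input, and the active-count-weighted
pooling then distorts the phase readout (quarter-wave sine fit R² ≈ 0.53,
readability 0.57); at the neutral point the chain is affine and the readout
is faithful (R² > 0.999, readability ≈ 0.90).  The target is an exposed
argument of every swim entry point.

**STP gain.**  The depression/facilitation imbalance is reduced to a single
derivative gain `k` (ms); the ~100 ms re-equilibration delay is absorbed
into it.  The default k = 10 ms keeps k·ω ≤ 0.63 for cycle wavelengths
≥ 100 ms — the regime where the millisecond shift is nearly
wavelength-independent (atan(kω)/ω ≈ k), which is the mechanism's proposed
function (cancelling a fixed conduction delay).

**Rolling-average edges.**  The 2 ms centred readout window shrinks at
sequence ends rather than discarding bins, so spike counts are conserved up
to edge effects.

**Reliability sweep.**  20 sinusoidal cycles (30–300 Hz) at 500 ms per
cycle, 10 replicate data sets per convergence ratio, all pairwise Pearson
correlations.  The period and replicate count are unreported choices.  The
mean pairwise correlation at ratio n behaves as ~1/(1 + c/n) with c ≈ 7.6
for the 2 ms window, i.e. it approaches but does not numerically reach 1 at
finite ratios (~0.985 at 500:1).

## Numerical choices

Bisection calibrates the gain on fixed granule wiring, which makes the
empirical active fraction exactly non-increasing in the gain; the search
asserts monotonicity and raises with diagnostics on degenerate inputs
(e.g. a constant-rate input is all-or-none at gain 1 and has no 50% point).
Dendrite wiring enforces distinct glomeruli per cell by redrawing the ~1% of
rows with repeats.  The STP time shift is located by circular
cross-correlation with parabolic sub-sample interpolation (waves must cover
≥ 2 full cycles); it matches atan(kω)/ω to <0.1% on pure sines.  All
randomness flows through explicit `numpy.random.Generator` objects, so a
seed reproduces every stage byte-for-byte.

## What the synthetic inputs do and do not emulate

Inputs are parameterized frequency-distribution snapshots (uniform, normal,
bimodal, discontinuous, constant) plus sinusoidal strip profiles emulating
proprioceptive drive during anguilliform swimming.  They capture the
*collective* statistics the model claims are functional, and nothing else:
no temporal correlation between snapshots, no burst structure, no
somatotopic fine structure within a strip, no feedback loops (the
granule→Golgi and parallel-fiber→Golgi refinements are deliberately
excluded), no learning dynamics, and no inter-network propagation — the
myomere→strip mapping is metadata on a single network's run.  Passing tests
therefore show that the sampling-chain arithmetic behaves as claimed under
the model's own idealizations, not that real cerebellar tissue does.

## Problem sizes

The canonical runs use the full anatomy: 100 fields × 8,750 granule cells
per strip, 41 strips per network (35.9 M granule cells per snapshot), 8,000
stellate and 400 Purkinje cells per microzone, 50 DCNs.  The statistical
suites use one strip where one strip suffices (regulation, tracking,
CLT chain), the full network for microzone synchrony and swimming (8-phase
sweeps at two wave fractions), and 10 replicates × 8 ratios × 10 s of
1 ms bins for the reliability curve.  Unit tests run a geometry-consistent
reduced network (9 strips × 20 fields × 400 cells).

## Known limitations

The model is a snapshot simulator of a hypothesis about collective rate
coding; it cannot address spike-timing codes, learning, or biophysical
nonlinearities by construction.  Quantities that depend on the unreported
spontaneous stellate rate (floor value), the straddle fraction, or the
inversion coefficients are sensitive to those defaults at extreme operating
points (very sparse codes, inputs at the scale boundaries).  Between-sector
structure — real, anatomy-driven variation between microfiles — places a
floor (~0.004–0.005 normalized) under Purkinje-soma synchrony that no
amount of within-sector averaging removes.
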