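# Methods

## Model overview

`rgcstim` simulates extracellular electrical stimulation of retinal ganglion
cells (RGCs) as three composable pieces: (1) a morphologically detailed,
conductance-based multi-compartment neuron; (2) an analytic disk-electrode
field imposed on the compartments; (3) search and population machinery that
turns spike/no-spike outcomes into thresholds, maps and recruitment curves.
Cells in a mosaic are electrically independent — they share the imposed field
but do not interact — so population simulations decompose into per-cell runs.

## Geometry and discretization

The retina lies in the x–y plane; +z points toward the vitreous and the
stimulating electrode, and the somatic center of the focal cell is at the
origin. Neurites are straight cylindrical sections organized in a tree. The
soma is a cylinder with length equal to its diameter, so its lateral area
`πd²` equals the surface area of the equivalent sphere. The axon leaves the
soma along +x in the retinal plane; the hillock is the first 50 µm of axonal
arc and the axon initial segment (AIS) spans path distances 25–75 µm from the
somatic center. The two definitions overlap for somas wider than ~0 µm; the
AIS label takes precedence in the overlap because its distinct conductances
are the physiologically meaningful feature. Axons are linearly extended
900 µm beyond their generated endpoint so they cross any electrode scan
region.

Sections are split into compartments strictly shorter than 12 µm (the
engine's accuracy was checked by re-segmenting at a third of that length:
compartment-size effects on thresholds are below 2%). Per-section membrane
area is conserved exactly under re-segmentation because cuts are equal-length
subdivisions of a constant-diameter cylinder.

### Synthetic morphology generator

Traced morphologies for this preparation are not publicly deposited, so the
package generates parametric stand-ins. The generator's contract covers the
features the analyses depend on: dendritic-field diameter (honored within
10%), planar stratification depth, soma-as-cylinder, hillock/AIS placement,
and an extended axon. Branching statistics are free: dendrites grow by
recursive bifurcation (three levels for large-field cells, two for
midget-like cells) with small seeded angular and radial jitter, tips placed
at the requested field radius.

Defaults define the standard large-field cell: 191 µm field, 25 µm soma,
dendrites stratified 10 µm below the somatic plane, four primary dendrites,
1 µm axon. Soma size and stratification depth are only loosely constrained
by the study system (large-field alpha-like mouse RGCs have 20–25 µm somas;
stratification is reported as a fraction of the inner plexiform layer, not
in µm). Within those anatomical ranges the defaults were calibrated, once,
so the synthetic cell reproduces the preparation's reported decoupling of
the dendritic tree from the AIS threshold (removing the dendrites or
doubling dendritic gNa moves the AIS threshold by only a few percent).
Smaller somas couple the dendritic arbor to the AIS much more strongly —
the arbor acts as a spatially extended "antenna" whose collected field
current dominates the drive — and removal effects then exceed 30%, which is
not what the study system shows. What passing tests on synthetic cells do
*not* show: reproduction of any threshold value tied to specific traced
morphologies; the generator emulates feature classes, not cells.

Mosaics tile one template cell on a rows×cols lattice (centered at the
origin) with i.i.d. Gaussian planar jitter, 5 µm SD for large-field cells
and 1 µm for midget-like cells. All cells share the template's axon
orientation (+x), emulating axons converging on the optic disk; this is what
creates passing axons under the test region. The coverage factor is
density × mean dendritic-field area, with the field taken as a circle of
the measured mean field diameter. The default 160 µm spacing for the 19- or
9-cell large-field mosaics yields a coverage factor of ≈1.2, inside the
1–3 "some overlap" regime reported for these cell types.

## Membrane biophysics

Each compartment carries the five-channel RGC complement: transient Na
(`m³h`), delayed-rectifier K (`n⁴`), A-type K (`a³h_A`), L-type Ca (`c³`)
and Ca-gated K, plus an ohmic leak. Region densities (mS/cm²):

| region   | gNa | gK | gA | gCa | gKCa  |
|----------|-----|----|----|-----|-------|
| dendrite | 40  | 12 | 36 | 2   | 0.05  |
| soma     | 70  | 18 | 54 | 1.5 | 0.065 |
| hillock  | 70  | 18 | 54 | 1.5 | 0.065 |
| AIS      | 700 | 18 | 54 | 1.5 | 0.065 |
| axon     | 70  | 18 | 0  | 0   | 0.065 |

with `gL = 0.005` everywhere, `ENa = 35`, `EK = −75`, `EL = −62.5` mV,
`Cm = 1 µF/cm²`, `Ra = 110 Ω·cm`. Dendritic gNa is adjustable (40–80) as a
pure table override. The leak is implemented as voltage-independent ohmic
conductance: no voltage dependence is specified for it and its reversal is
a fixed −62.5 mV.

Gating kinetics are the classic RGC rate-function set of the
Fohlmeister-lineage formalism, kept in one editable kinetics table
(`rgcstim.channels.KINETICS`) together with the adopted calcium-pool
constants: residual 10⁻⁴ mM, external 1.8 mM, removal time constant 1.5 ms,
submembrane shell depth 0.1 µm (capped at the compartment radius), K(Ca)
half-activation 10⁻³ mM with Hill exponent 2. The calcium reversal follows
the pool through the Nernst relation, so ECa falls as calcium accumulates.

Two calibration entries in the table deserve explanation:

- `na_act_shift = +2 mV` — with the published room-temperature rates and the
  fixed leak reversal of −62.5 mV, the steady-state Na window current is net
  inward above ≈−64 mV in every region (overwhelmingly so at the gNa = 700
  AIS), which turns the cell into a ~5 Hz intrinsic pacemaker. The study's
  protocols presuppose a cell that is silent at rest (40 ms stimulus windows,
  0 mV crossing detection). A +2 mV depolarizing shift of the Na activation
  curve closes the window at rest while leaving inactivation, spike height
  and repetitive firing intact: the standard cell is then quiescent for at
  least 2 s (<0.5 mV drift), rests at −63.8 mV (within 1.5 mV of EL), and
  fires repetitively with monotonically decreasing inter-spike intervals for
  10–60 pA somatic injections.
- `rate_scale = 1.0` — rates are applied as published (room temperature),
  with the nominal 35 °C recorded as metadata. Uniform Q10 scaling (×2–3.5)
  was evaluated and rejected: it truncates action-potential peaks below the
  0 mV detection criterion and suppresses injected repetitive firing, and
  correcting that would require re-balancing the published conductance
  densities. The practical consequence is that response latencies are ~3–4×
  longer than at physiological temperature (AIS-stimulation latency ≈1.3 ms
  rather than ≈0.3 ms); latency *orderings* (AIS < soma < dendrite
  stimulation) are preserved.

## Cable engine

Axial conductances follow from `Ra` and the cylinder geometry as series
half-compartment resistances; capacitance and channel conductances scale
with lateral membrane area; boundary conditions are sealed ends. Voltage is
advanced by Crank–Nicolson with the gates updated by their exact exponential
relaxation (staggered, using the pre-step voltage) and the calcium pool by
the exact solution of its linear ODE. The tree-structured linear system is
solved in O(N) by Hines elimination (compartments are ordered parent-first);
a dense solve is available for verification and agrees to <10⁻¹⁰ mV.
`dt = 0.025 ms`; halving it changes thresholds of the standard cell by <2%.

Extracellular coupling: the field is sampled at compartment midpoints and
enters as equivalent current sources `Σⱼ gᵢⱼ(Veⱼ − Veᵢ)` on the axial
branches, time-centered across the step. Only spatial *differences* of Ve
drive the membrane — a uniform Ve(t) produces exactly zero response, which
is the engine's key sanity check. The potential is assumed constant across
each compartment's cross-section (1-D cable approximation); this degrades
for electrodes much closer than a compartment diameter.

Initialization: every protocol starts from a rest state obtained by 200 ms
of stimulus-free settling from EL (cached per model). The integrator is
strictly sequential and deterministic, so repeated runs — and runs
distributed over worker processes — are bitwise identical.

## Extracellular field

The electrode is a monopolar, purely resistive disk in an isotropic ohmic
medium. The potential is the oblate-spheroidal (Newman) disk solution
normalized so that the disk surface sits at `V = I·Rs`, where `Rs` is the
calibrated electrode transfer resistance (0.725 for the 10 µm reference
electrode 40 µm above the cell; other sizes by surface-area scaling
`(a₀/a)²`). Unit convention: stimulus currents are expressed in µA and the
calibrated `Rs` value converts µA to *volts* of surface potential (i.e. the
number 0.725 is effectively in MΩ). This is the only reading under which
µA-scale currents produce the tens-of-mV fields that excite neurons; taking
the printed value literally in ohms yields sub-µV fields and no excitation
at any plausible current.

Depth-dependent tissue inhomogeneity multiplies `Rs` by
`C(z) = 1/ratio + (1 − 1/ratio)·exp(−(z/width)²)` with width 20 µm (somatic
layer scale), so `C(0) = 1` (peak resistivity at the somatic layer equals
`Rs`) and `C → R_distant/R_peak` far from it. Because the cell spans depth
(axon at z ≈ 0, dendrites stratified below), a depth-varying C adds
potential *gradients* across the cell; empirically this lowers thresholds —
most strongly for dendritic stimulation sites and least at the AIS, which
stays the global threshold minimum, matching the study system's robustness
finding. Note that the absolute normalization of C is a pure rescaling of
`Rs`; only the relative, between-region comparison is meaningful.

The stimulus is a charge-balanced cathodic-first biphasic pulse, 0.1 ms per
phase, no inter-phase gap, onset 1 ms into each 40 ms run (the pre-stimulus
baseline aids spike discrimination; the models are spontaneous-spike-free).
Cathodic current is signed negative.

## Thresholds and spike criteria

Spikes are detected as upward 0 mV crossings of the somatic membrane
potential, one event per contiguous suprathreshold run, timed at the local
maximum. An *evoked* spike must additionally peak after the biphasic pulse
has ended: near the electrode, strong fields can transiently polarize the
soma above 0 mV during the pulse itself without triggering a regenerative
action potential, and counting that passive transient would misclassify
pure field artifacts as spikes.

`find_threshold` brackets the threshold by doubling from 1 µA (cap 200 µA —
positions that fail at the cap are reported not-excitable, not errors) and
bisects until the bracket is within tolerance: 0.1 µA for the 10 µm
electrode, 0.5 µA for larger ones. The returned value is the spiking upper
bracket, so threshold stimulation always spikes. The final bracket is
re-probed as a monotonicity check; a non-monotone position would be
re-scanned linearly at tolerance resolution and flagged. Threshold maps run
an independent search per grid position (10 µm default step, electrode
40 µm above the somatic plane); positions are independent, so serial and
parallel scans agree exactly. The AIS threshold of a cell is the mean over
searches at the proximal end, midpoint and distal end of the AIS.

## Population analysis

The population threshold at a position is the minimum current activating at
least one cell of the mosaic (binary search on the activated-set size; all
mosaic cells are simulated, including those outside the test region). The
activated set "at threshold" is evaluated at the spiking upper bracket,
guaranteeing ≥1 active cell. Because the field depends only on the
electrode–cell offset, each cell is simulated by shifting the electrode into
the template frame; one cable model (and one cached rest state) serves the
whole mosaic. Identity maps key on sorted cell-id tuples;
distance-to-nearest-axon uses in-plane point-to-polyline distance;
supra-threshold sweeps record each activated cell's spike-initiation
compartment, which distinguishes somatic-region activation from
passing-axon recruitment.

## Problem sizes and runtime

The standard cell discretizes to ~200 compartments; a 40 ms run takes a few
milliseconds, a threshold search tens of milliseconds, and the test suite's
maps use 20–40 µm grids of 24–48 positions (minutes on one CPU). The 9-cell
mosaic analyses use a 30-position interior grid. These sizes were chosen so
the full verification cycle runs comfortably on a laptop-class machine; the
algorithms themselves scale linearly in compartments and positions and the
position loop parallelizes process-wise.

## Known limitations

- Synthetic morphologies emulate feature classes (field size, AIS geometry,
  stratification), not traced cells; quantities tied to specific traced
  morphologies are out of reach by construction.
- Room-temperature kinetics inflate latencies ~3–4× (orderings preserved).
- No electrode–electrolyte dynamics, capacitive charge injection, or
  anisotropic conductivity; the electrode is purely resistive.
- No synaptic network, ephaptic coupling, or myelination; cells are
  independent and axons unmyelinated, per the modeled preparation.
- Strength–duration behavior and multi-pulse protocols are not modeled; the
  stimulus is the single 0.1 ms/phase biphasic pulse.
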