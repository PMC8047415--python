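# Methods

`reentrylab` is a desk-scale workbench for studying how the choice of an
arrhythmia-induction protocol shapes the assessment of atrial-fibrillation
vulnerability in silico. It replaces patient-derived bi-atrial geometries
with synthetic 1D strands and 2D sheets, so every protocol behavior —
refractory-period search, per-beat arrhythmia checking, spiral seeding,
phase-singularity classification — can be exercised, tested and reproduced
on a laptop. This note documents the models, the numerical choices, and
what the synthetic substrates do and do not show about real atria.

## Tissue model

The transmembrane voltage obeys the monodomain reaction–diffusion equation

    dV/dt = ∇·(D ∇V) − I_ion/C_m + I_stim/C_m,   D = σ / (β C_m),

with surface-to-volume ratio β = 0.14 µm⁻¹ and specific capacitance
C_m = 1 µF/cm² (both configurable; the values follow the membrane
model's own conventions). σ is the bulk conductivity in S/m,
stored per element; a conductivity of 0.14 S/m corresponds to
D = 0.1 mm²/ms.

Discretization: node-centered regular grid (spacing `h`, default 0.5 mm on
sheets, 0.25 mm on tuning strands), 5-point (3-point in 1D) explicit
diffusion stencil with **harmonic-mean face conductivities** — an element
with σ = 10⁻⁷ S/m therefore blocks flux through its faces, which is how
percolation-type fibrotic decoupling is represented without removing
elements. Boundaries are no-flux. Time integration is operator-split:
diffusion (forward Euler) then the ionic step, at dt = 0.02 ms by default.
A CFL-type guard (`dt·D·2·axes/h² ≤ 1`) rejects unstable configurations up
front, and the solver aborts with a diagnostic if |V| exceeds 200 mV.
Identical inputs produce bit-identical voltage movies.

Stimuli are transmembrane current injections over a square footprint
(default 2 × 2 mm, 30 µA/cm², 2 ms). With C_m = 1 µF/cm² the current
density equals 30 pA/pF in the ionic equation. The stimulus duration defaults to 2 ms and is
configurable.

## Membrane models

**Detailed model.** The Courtemanche–Ramirez–Nattel human atrial myocyte
model (21 states, 12 membrane currents, SR calcium handling) is
implemented as a numba kernel with Rush–Larsen exponential updates for the
15 gating variables and forward Euler for voltage and concentrations. The
implementation reproduces the canonical resting state (−81.2 mV, drift
< 0.01 mV over 10 s), an upstroke to +40 mV, and APD94 ≈ 325 ms at a
single paced beat. dt ≤ 0.05 ms is enforced.

**Remodeling presets** rescale maximal conductances:

* `control` — identity.
* `cytokine_fibrotic` — the cytokine-related remodeling applied to
  conducting fibrotic tissue: g_K1 × 0.5, g_Na × 0.6, g_CaL × 0.5. These
  three factors are the fixed, defining parameterization of the preset.
* `AF` — chronic-AF electrical remodeling. No single parameter set is
  canonical, so the preset is configurable; the defaults (g_CaL × 0.3, g_to × 0.5, g_Kur × 0.5, g_K1 × 2.0) follow the
  widely used chronic-AF adaptation of the same membrane model and yield
  APD94 ≈ 152 ms vs 325 ms control, with cell ERP shortened accordingly.

**Fast phenomenological model** (`fast_test`): a three-current
Fenton–Karma-type model (fast inward, slow ungated outward, slow inward)
with voltage mapped to mV via V = −85 + 100·u. The parameter set was
chosen so that 2D sheets support both stable spiral re-entry and
point-source ignition from the standard 2 × 2 mm stimulus. Two deliberate
deviations from a textbook implementation:

* the excitation variable is clamped to [−0.05, 1.05] (V ∈ [−90, +20] mV).
  The plateau of this parameter set is a near-balance of the slow inward
  and outward currents; rescaling the repolarizing current can otherwise
  push u far above 1. The clamp bounds the voltage for every preset.
* conductance scales are rendered sparsely: only g_K1 acts (on the plateau
  repolarizing time constant, with square-root attenuation because the
  lumped current responds much more steeply than a real conductance), and
  the rest are identity. Scaling the fast inward current pushes this
  parameter set past its propagation limit, so a "cytokine" fast-model
  tissue is slower to repolarize but not slower to conduct. Where
  conduction slowing matters, tests use the detailed model.

The fast model is used wherever full ionic detail is not the point:
2D induction fixtures, ERP-search oracles, phase-analysis movies. The
conductivity-tuning targets (primary calibration quantities) always run
on the detailed model.

## Geometry, fibrosis, pacing sites

Domains are strands and sheets; a two-region sheet with named halves
("LAW"/"RAW") stands in for the left/right atrial walls. Fibrosis presets
UII (19% LAW, 5% RAW) and UIV (39% LAW, 11% RAW) select
`round(fraction × |region|)` elements per region by uniform sampling
without replacement — exact counts, not expectations — and set exactly
half of them to σ = 10⁻⁷ S/m (passive barriers); the remainder conduct
with the cytokine membrane preset. Sampling is deterministic in the preset
seed. The spatial texture of real fibrosis (clustering, transmurality) is
not modeled; uniform scattering is the documented choice.

Pacing sites form a regular grid (default 10 mm spacing, 5 mm boundary
margin) snapped to conductive nodes; a candidate on a barrier moves to the
nearest conductive node within half the grid spacing or is dropped and
recorded. Spatial segments are k × k equal-area blocks (the anatomical
28-segment parcellation is geometry-specific and out of scope); they
partition the element set exactly.

Geodesic distances run through conductive tissue on the 8-neighbor node
graph (scipy Dijkstra); on obstacle-free convex domains they agree with
straight lines to within one grid diagonal.

## Induction protocols

All protocols share one backend interface (deliver a beat at a coupling
interval, probe a trial beat with rollback, run the induction check), so
the engines are unit-testable against scripted stubs while
`MonodomainBackend` supplies the full tissue behavior.

**Rapid pacing (RP).** The train for parameters (s, l, step, N) is each
coupling interval from s down to l duplicated N times; the first stimulus
is delivered immediately and each subsequent one its own CI after the
previous. Mode E runs the whole train and checks once; mode B pauses after
every beat, runs the induction check from a checkpoint, stops at the first
success and otherwise resumes from the checkpoint. Control and
AF-remodeled phenotypes default to (s, l) = (300, 200) and (200, 130) ms
with 10 ms decrements.

**Local propagation criterion.** A beat counts as locally propagating
when a *new* depolarization reaches a ring of conductive nodes at geodesic
distance 4–6 mm from the site within an 80 ms observation window:
specifically, a rising crossing of −50 mV at a ring node that is absent
(or ≥ 10 ms later) in a paired reference simulation run from the same
state without the stimulus. The paired reference is essential on fibrotic
substrates, where the previous beat's wave can still be in transit through
the ring and would otherwise be credited to the new stimulus. The 80 ms
window covers 6 mm at conduction velocities down to ~0.1 m/s.

**ERP search (PEERP).** The tissue effective refractory period after each
beat is the smallest propagating coupling, found by bisection starting
from the bracket [guess/2, guess] with the APD94 of the paced membrane as
first guess (rendered as steady 1 Hz pacing); a failing upper edge expands
× 1.5 up to 3 × guess, then the site is reported non-capturing. Trial
beats run from a checkpoint and are rolled back, so probing never
perturbs the tissue history. If the probes contradict monotonicity
(capture at c, none at c′ > c), a warning is raised and an exhaustive
linear scan decides. When the bracket floor itself propagates the floor is
returned: shorter couplings cannot be discriminated from the previous
beat's transit, and the next beat's warm-started guess adapts downward.
PEERP then delivers up to `max_beats` (default 4) stimuli, each at the
measured ERP, checking for induction after every beat.

**Induction criterion.** A site is inducing when activity is sustained for
1.5 s after the protocol ends. Operationally, over every output frame of
the 1.5 s continuation: (a) at least one conductive node sits at or above
−50 mV, and (b) a new activation (rising −40 mV crossing) occurs somewhere
in every rolling 500 ms window. Part (b) distinguishes sustained
propagation from a hung depolarized plateau. The criterion inspects the
whole domain, and the boundary is inclusive: quiescence exactly at
1 500 ms fails. The continuation used by a successful mode-B check is the
final 1.5 s itself; failed checks are rolled back.

**PSD seeding.** Reentry is initialized directly by constructing the
activation-time map

    T(x) = mod( CL·θ(x)/2π + D(x)/v , CL ),

where θ is the winding angle around the seeded core (anticlockwise =
positive winding in the sheet's standard orientation; the endo/epi
viewpoint has no meaning on a 2D sheet), D the eikonal distance from the
core computed by first-order fast marching through conductive tissue, and
v the conduction speed (default: the measured strand CV of the active
membrane/conductivity). Published descriptions of this construction
are under-specified; the additive angle-plus-eikonal form is this
package's documented interpretation, chosen because it provably carries exactly one
phase singularity of the requested chirality. The map is converted to a
tissue state by sampling a steady-pacing limit cycle (≥ 20 conditioning
beats, beat-to-beat APD94 alternans > 5 ms triggers a warning) at phase
−T(x) per node; barriers rest. The reentry cycle length follows the 5%
rule: CL = round(1.05 × ERP) — 315 ms for a control ERP of 300 ms, 168 ms
for the AF-variant ERP of 160 ms.

## Phase analysis and episode classification

Phase is computed by time-delay embedding,
φ = atan2(V(t) − V*, V(t − τ) − V*), with τ = 10 ms and per-node mean V*
over the analysis window (both configurable); quiescent nodes (< 1 mV
excursion) are masked. Several variants of this embedding exist in the
detection literature; this one is the package's declared choice. Phase singularities are plaquette defects: the
wrapped phase circulation around each elementary grid cell equals ±2π at a
core (topological charge ±1); boundary plaquettes and masked nodes are
excluded. Detections are linked frame to frame by greedy nearest-neighbor
association among same-charge detections within a speed gate (default
1 m/s), distance-then-index tie-broken, with optional 1-frame gap
bridging (off by default).

Episode taxonomy: an llPS is a trajectory with lifetime ≥ 500 ms; it is
*stable* when it spans the entire final 1.5 s and its path there fits in
an axis-aligned 5 cm square. Induced episodes without any llPS are split
by an explicit heuristic in place of expert visual inspection: flutter
(Fl) when per-node activation intervals are regular (coefficient of
variation < 0.1, each node's first interval dropped as induction
transient) and the mean number of simultaneous wavefronts is ≤ 2;
otherwise multiple wavefronts (Multi). Wavefronts are 8-connected
components of upward −40 mV crossings pooled over 10 ms windows (a front
moving less than one cell per frame would otherwise fragment). All
thresholds are keyword arguments and recorded in outputs.

## Vulnerability maps and sensitivity procedures

`run_vulnerability_map` probes every pacing site independently from the
same rested state, classifies each induced episode, finds the segment
anchoring any stable llPS (segment of the path center over the final
1.5 s) and the geodesic distance from the inducing site to that center.
Spacing sensitivity thins the site grid to 15/20/25/30 mm subsets (greedy
minimum-distance selection) and reports the percentage of the full map's
stable-llPS segments recovered — no re-simulation is needed because sites
are independent. The ERP-tolerance sweep re-runs the PEERP map with the
binary search stopped at 1–8 ms resolution; the stability of the
inducing-point count is the readout.

## Synthetic substrates (fixtures)

The substrates in `reentrylab.fixtures` define the package's study
conditions:

* `flutter_loop_substrate` — a 6 cm sheet (σ = 0.15 S/m, fast model with
  g_K1 × 1.3 for a ~45 mm wavelength) with a 2-element-thick nonconductive
  line across the center and a slower-recovery region below-right of the
  pacing site. Premature beats at the measured ERP block into the
  slow-recovery side, travel around the line and re-enter; PEERP induces a
  sustained macro-reentry (cycle length ≈ 650 ms, one circulating
  wavefront) within 3 beats.
* `gradient_sheet_substrate` — a step in repolarization rate between the
  sheet halves, for vulnerable-window experiments.
* `fibrotic_two_region_sheet` — the UII/UIV presets on a two-region sheet.
* `erp_strand` — a 4 cm strand for refractory-period experiments.

What these substrates show: that the protocol logic (timing, block,
re-entry, classification) behaves mechanistically as described. What they
do not show: clinical inducibility rates. Wavelengths, anisotropy, wall
thickness, anatomical obstacles and the fibrosis texture of real atria are
absent, so absolute counts of inducing points or episode-class frequencies
on these sheets say nothing quantitative about patient geometries.

## Problem sizes and tolerances

Default problem sizes were chosen so the full test suite and the
acceptance script each finish comfortably on one CPU: conductivity tuning
on a 5 cm / 0.25 mm strand (201 nodes, dt 0.02 ms, bisection tolerance
0.01 m/s, ~10 strand simulations); spiral and induction fixtures on
121–141 node sheets at dt 0.05–0.1 ms for the fast model. The fast model
tolerates dt up to ~0.1 ms; its conduction velocity converges to < 1%
between h = 0.25 and 0.125 mm, and the √σ scaling of CV holds to < 5% at
h = 0.25 mm. First-order fast marching agrees with an 8-neighbor Dijkstra
oracle within the combined metrication band (~8%).

## Known limitations

* 2D isotropic sheets only; fiber anisotropy is plumbed (per-element
  angle, conductivity ratio) but not exercised by the shipped fixtures.
* The fast model's preset rendering is qualitative by design (see above);
  quantitative remodeling claims require the detailed membrane model.
* The mode-B intermediate induction checks use the full 1.5 s criterion;
  this makes per-site simulated-time accounting internally consistent but
  more expensive than a shorter intermediate check would be.
* Phase-singularity positions are quantized to plaquette centers (half a
  grid cell); sub-cell core localization is not attempted.
* Episode classification thresholds (CV < 0.1, ≤ 2 wavefronts) are an
  algorithmic stand-in for expert visual inspection; borderline episodes
  (e.g. a slightly irregular macro-reentry) can flip between Fl and Multi.
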