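# reentrylab

A desk-scale workbench for in-silico atrial arrhythmia vulnerability:
monodomain tissue simulation on synthetic 1D/2D domains, the three
standard induction protocols, and phase-singularity-based classification
of the induced episodes.

Whether a computational atrial model is "inducible" depends strongly on
*how* you try to induce arrhythmia. This package implements the competing
protocols side by side so their behavior can be compared reproducibly,
without MRI-derived geometries:

* **PEERP** — pacing at the end of the effective refractory period. Each
  stimulus is delivered at the earliest coupling at which a new wave
  locally propagates (transmembrane potential ≥ −50 mV in a ring 4–6 mm
  around the site), found by a run-time binary search with 1 ms
  resolution, starting from APD₉₄ as first guess. The only protocol
  parameter is the beat budget (default 4).
* **RP** — rapid pacing: trains RP(s→l, N, B/E) of stimuli with coupling
  intervals decremented from *s* to *l* in 10 ms steps, *N* beats per CI,
  checking for arrhythmia after every beat (B) or at the end (E). Defaults
  are (300, 200) ms for control and (200, 130) ms for AF-remodeled tissue.
* **PSD** — phase-singularity distribution: reentry is seeded directly by
  building a spiral activation-time map T(x) = mod(CL·θ/2π + D/v, CL)
  around a chosen core (eikonal distance D by fast marching) and mapping
  it through a steady-pacing limit cycle; CL = 1.05 × ERP.

A site is *inducing* when activity is sustained ≥ 1.5 s after the protocol
ends. Episodes are typed by their tracked phase singularities — charge ±1
defects of the time-delay-embedding phase — into stable llPS (a PS lives
≥ 500 ms and stays within a 5 cm box over the final 1.5 s), non-stable
llPS, flutter (periodic, ≤ 2 wavefronts) or multiple wavefronts.

The membrane kinetics are the Courtemanche–Ramirez–Nattel human atrial
model with control / chronic-AF / cytokine-fibrotic conductance presets,
plus a fast 3-variable phenomenological model for protocol-logic studies.
Fibrotic substrates follow the Utah-stage presets (UII: 19%/5%, UIV:
39%/11% of the left/right walls) with half of the fibrotic elements as
percolation barriers (σ = 10⁻⁷ S/m) and half cytokine-remodeled
(−50% g_K1, −40% g_Na, −50% g_CaL).

## Worked example

Induce re-entry with PEERP on a sheet with a line of conduction block and
a slow-recovery region (`examples/peerp_induction.py`):

```text
induced: True after 3 beats
  beat 0: coupling    0.0 ms, propagated=True
  beat 1: coupling  174.7 ms, propagated=True
  beat 2: coupling   87.3 ms, propagated=True
total simulated time: 8.1 s
episode class: Fl (cycle length 650 ms, 1.1 simultaneous wavefronts)
```

Beat 1 lands at the measured tissue ERP (174.7 ms) and blocks into the
slow-recovery region; beat 2, delivered at the much shorter post-premature
ERP, completes the unidirectional block and the wave circulates around the
barrier — a flutter-like macro-reentry with a 650 ms cycle and a single
wavefront. Contrast this with the rapid-pacing modes on the same substrate
(`examples/rapid_pacing_modes.py`):

```text
mode B: induced=True beats=3 inducing CI=210.0 simulated 5.5 s
mode E: induced=True beats=9 inducing CI=150.0 simulated 4.0 s
```

Mode B stops at the first inducing coupling interval; mode E pays fewer
induction checks but delivers the full train, and later stimuli can even
terminate an episode induced earlier.

Other example scripts: single-cell action potentials of the three
membrane presets, conduction-velocity tuning, fibrotic substrate
construction, and PSD spiral seeding with phase-singularity tracking.

A thin CLI mirrors the library (`reentrylab simulate|erp|peerp|rp|psd|
analyze-ps|vulnmap|make-fixture`), reading a YAML run configuration and
writing JSON/CSV/legacy-VTK/HDF5 outputs stamped with the config hash.

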