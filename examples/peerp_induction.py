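"""Inducing re-entry by pacing at the end of the effective refractory
period (PEERP).

On a substrate with a linear line of conduction block and a slow-recovery
region, each PEERP beat is delivered at the earliest locally propagating
coupling (run-time binary search, 1 ms resolution).  A premature beat
blocks into the slow-recovery side, circulates around the line and
re-enters: a sustained macro-reentrant (flutter-like) episode.
"""

from reentrylab import fixtures, phase, protocols

geom, model, scales, site = fixtures.flutter_loop_substrate()
backend = protocols.MonodomainBackend(geom, model, site, dt=0.1,
                                      node_scales=scales)
params = protocols.PEERPParams(max_beats=4, erp_first_guess=172.0)
res = protocols.run_peerp(backend, params)

print(f"induced: {res.induced} after {res.beats_delivered} beats")
for beat in res.per_beat:
    print(f"  beat {beat['beat']}: coupling {beat['ci']:6.1f} ms, "
          f"propagated={beat['propagated']}")
print(f"total simulated time: {res.simulated_ms / 1000:.1f} s")

cont = res.continuation
ph, _ = phase.compute_phase(cont.vm, cont.dt_out)
lag = cont.vm.shape[0] - ph.shape[0]
dets = [phase.detect_ps(ph[k], h=geom.h) for k in range(ph.shape[0])]
trajs = phase.track_ps(dets, cont.times[lag:], v_max=1.0)
episode = phase.classify_episode(cont.vm, cont.times, trajs,
                                 induced=res.induced, h=geom.h)
print(f"episode class: {episode.label} "
      f"(cycle length {episode.cycle_length_ms:.0f} ms, "
      f"{episode.mean_wavefronts:.1f} simultaneous wavefronts)")

# PEERP needs no protocol parameters beyond the beat budget: the coupling
# of every beat adapts to the measured local refractoriness.
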