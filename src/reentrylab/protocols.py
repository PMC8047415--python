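"""Arrhythmia induction protocols.

Two pacing protocols are implemented over a common backend interface:

* **RP** (rapid pacing): a train of stimuli with coupling intervals (CIs)
  decremented from ``s`` to ``l`` in fixed steps, ``N`` beats per CI, and
  arrhythmia checking either after every beat (mode ``B``) or only at the
  end of the train (mode ``E``).
* **PEERP** (pacing at the end of the effective refractory period): each
  beat is delivered at the earliest coupling at which a new wave locally
  propagates, found by a run-time binary search with 1 ms resolution; the
  search predicate is a transmembrane potential >= -50 mV in at least one
  node of a ring 4-6 mm around the stimulation site.

A site is *inducing* when the protocol initiates activity that is
sustained for at least 1.5 s after the protocol ends: every output frame
of the continuation shows >= 1 conductive node at Vm >= -50 mV, and a new
activation (rising -40 mV crossing) occurs somewhere in every rolling
500 ms window (a hung depolarized plateau does not count).

The protocol engines talk to a backend exposing beat delivery with
checkpoint/rollback, so deterministic scripted stubs can drive the control
flow in tests while :class:`MonodomainBackend` runs the full tissue model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.sparse.csgraph import dijkstra

from . import ionic, monodomain
from .geometry import TissueGeometry, _conductive_graph

__all__ = [
    "RPParams",
    "PEERPParams",
    "ProtocolResult",
    "InductionBackend",
    "MonodomainBackend",
    "build_rp_train",
    "run_rp",
    "run_peerp",
    "find_erp",
    "propagation_check_movie",
    "sustained_activity",
    "ring_mask",
]


@dataclass
class RPParams:
    """Rapid-pacing train: CIs from ``s`` down to ``l`` in ``step`` ms
    decrements, ``n_per_ci`` stimuli per CI, check mode ``B`` or ``E``."""

    s: float
    l: float  # noqa: E741 - protocol notation
    step: float = 10.0
    n_per_ci: int = 1
    check_mode: str = "E"

    def __post_init__(self) -> None:
        if self.s < self.l:
            raise ValueError(f"starting CI {self.s} must be >= last CI {self.l}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_per_ci < 1:
            raise ValueError("n_per_ci must be >= 1")
        if self.check_mode not in ("B", "E"):
            raise ValueError(f"check mode must be 'B' or 'E', got {self.check_mode!r}")


def control_rp_params(**kw) -> RPParams:
    """Control-phenotype defaults: CI from 300 down to 200 ms."""
    return RPParams(s=300.0, l=200.0, **kw)


def af_rp_params(**kw) -> RPParams:
    """AF-remodeled-phenotype defaults: CI from 200 down to 130 ms."""
    return RPParams(s=200.0, l=130.0, **kw)


@dataclass
class PEERPParams:
    """PEERP settings; the only protocol parameter is the beat budget."""

    max_beats: int = 4
    erp_resolution: float = 1.0
    ring_mm: tuple[float, float] = (4.0, 6.0)
    threshold_mv: float = -50.0
    erp_first_guess: float | None = None   # defaults to APD94 of the membrane

    def __post_init__(self) -> None:
        if self.max_beats < 0:
            raise ValueError("max_beats must be >= 0")
        if self.erp_resolution < 0.5:
            raise ValueError("erp_resolution must be >= 0.5 ms")
        if self.ring_mm[0] >= self.ring_mm[1]:
            raise ValueError("ring inner radius must be < outer radius")


@dataclass
class ProtocolResult:
    induced: bool
    beats_delivered: int
    inducing_ci: float | None
    per_beat: list[dict] = field(default_factory=list)
    simulated_ms: float = 0.0
    continuation: object | None = None     # SimulationResult of the final check
    status: str = "ok"


# ---------------------------------------------------------------------------
# backend interface


@runtime_checkable
class InductionBackend(Protocol):
    """Minimal surface the protocol engines require."""

    def deliver_beat(self, ci: float) -> bool:
        """Deliver the next stimulus ``ci`` ms after the previous one
        (immediately for the first beat); returns the propagation flag."""
        ...

    def trial_beat(self, ci: float) -> bool:
        """Like :meth:`deliver_beat` but rolled back afterwards."""
        ...

    def check_induction(self) -> bool:
        """Continue 1.5 s past the last beat and evaluate the sustained-
        activity criterion; tissue history is left unchanged."""
        ...

    @property
    def simulated_ms(self) -> float: ...


# ---------------------------------------------------------------------------
# RP


def build_rp_train(params: RPParams) -> list[float]:
    """Expand RP parameters into the full list of coupling intervals."""
    span = params.s - params.l
    n_dec = span / params.step
    if abs(n_dec - round(n_dec)) > 1e-9:
        raise ValueError(
            f"CI span {params.s}-{params.l} not divisible by step {params.step}"
        )
    cis = [params.s - k * params.step for k in range(int(round(n_dec)) + 1)]
    return [ci for ci in cis for _ in range(params.n_per_ci)]


def run_rp(backend: InductionBackend, params: RPParams) -> ProtocolResult:
    """Execute a rapid-pacing train on ``backend``.

    Mode ``B`` pauses after every beat to run the induction check and stops
    at the first success; mode ``E`` delivers the full train and checks
    once at the end.
    """
    train = build_rp_train(params)
    per_beat: list[dict] = []
    induced = False
    inducing_ci: float | None = None
    for k, ci in enumerate(train):
        propagated = backend.deliver_beat(ci)
        per_beat.append({"beat": k, "ci": ci, "propagated": bool(propagated)})
        if params.check_mode == "B":
            if backend.check_induction():
                induced = True
                inducing_ci = ci
                break
    if params.check_mode == "E":
        induced = backend.check_induction()
        if induced:
            inducing_ci = train[-1]
    return ProtocolResult(
        induced=induced,
        beats_delivered=len(per_beat),
        inducing_ci=inducing_ci,
        per_beat=per_beat,
        simulated_ms=backend.simulated_ms,
        continuation=getattr(backend, "last_continuation", None),
    )


# ---------------------------------------------------------------------------
# ERP binary search


def find_erp(
    backend: InductionBackend,
    guess: float,
    resolution: float = 1.0,
    max_expand: int = 8,
) -> float:
    """Smallest propagating coupling after the previous beat, by bisection.

    Starts from the bracket ``[guess/2, guess]``; the upper edge is
    expanded by x1.5 while it fails to propagate (up to 3x the guess).
    Trial beats run from a checkpoint, so probing leaves no trace in the
    tissue history.  If the recorded probes contradict monotonicity a
    warning is issued and an exhaustive linear scan decides.
    """
    if guess <= 0:
        raise ValueError("ERP guess must be positive")
    probes: dict[float, bool] = {}

    def prop(c: float) -> bool:
        c = round(c, 6)
        if c not in probes:
            probes[c] = backend.trial_beat(c)
        return probes[c]

    def audited(result: float) -> float:
        # monotonicity audit over everything probed; on violation an
        # exhaustive scan from the bracket floor decides
        passes = sorted(c for c, p in probes.items() if p)
        fails = sorted(c for c, p in probes.items() if not p)
        if passes and fails and passes[0] < fails[-1]:
            warnings.warn(
                "capture predicate not monotone over probed couplings "
                "(supernormality?); falling back to linear scan",
                stacklevel=3,
            )
            c = guess / 2
            while c <= 3 * guess:
                if prop(round(float(c), 6)):
                    return float(c)
                c += resolution
            raise RuntimeError("linear scan found no propagating coupling")
        return result

    hi = float(guess)
    n_exp = 0
    while not prop(hi):
        hi *= 1.5
        n_exp += 1
        if hi > 3 * guess or n_exp > max_expand:
            raise RuntimeError(
                f"no propagation at any coupling up to {hi / 1.5:.0f} ms "
                f"(guess {guess:.0f} ms)"
            )
    lo = guess / 2
    if prop(lo):
        # ERP is at or below the bracket floor; shorter couplings cannot be
        # distinguished from the previous beat's wave transit, so report the
        # floor (the next beat's warm-started guess adapts downward)
        return audited(lo)
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if prop(mid):
            hi = mid
        else:
            lo = mid
    return audited(hi)


# ---------------------------------------------------------------------------
# PEERP


def run_peerp(backend: InductionBackend, params: PEERPParams) -> ProtocolResult:
    """Pace at the end of the effective refractory period.

    The first beat lands on recovered tissue; every subsequent beat is
    delivered at the ERP measured from the current tissue state.  After
    each beat the induction check runs; the protocol stops at induction or
    at ``max_beats``.
    """
    per_beat: list[dict] = []
    induced = False
    inducing_ci: float | None = None
    guess = params.erp_first_guess
    if guess is None:
        raise ValueError("erp_first_guess is required (use APD94 of the membrane)")
    status = "ok"
    for k in range(params.max_beats):
        if k == 0:
            propagated = backend.deliver_beat(0.0)
            ci = 0.0
        else:
            try:
                ci = find_erp(backend, guess, params.erp_resolution)
            except RuntimeError as exc:
                status = f"non-capture at beat {k}: {exc}"
                break
            guess = ci  # warm start the next search
            propagated = backend.deliver_beat(ci)
        per_beat.append({"beat": k, "ci": ci, "propagated": bool(propagated)})
        if backend.check_induction():
            induced = True
            inducing_ci = ci if k > 0 else None
            break
    return ProtocolResult(
        induced=induced,
        beats_delivered=len(per_beat),
        inducing_ci=inducing_ci,
        per_beat=per_beat,
        simulated_ms=backend.simulated_ms,
        continuation=getattr(backend, "last_continuation", None),
        status=status,
    )


# ---------------------------------------------------------------------------
# induction criterion and propagation check


def sustained_activity(
    vm: np.ndarray,
    times: np.ndarray,
    conductive: np.ndarray,
    horizon_ms: float = 1500.0,
    activity_threshold: float = -50.0,
    upstroke_threshold: float = -40.0,
    max_quiet_ms: float = 500.0,
) -> bool:
    """Two-part sustained-activity rule on a continuation movie.

    ``vm``: (frames, ...) movie starting at the protocol end; ``times``
    relative to the protocol end.  True iff (a) at every frame in
    ``(0, horizon]`` at least one conductive node is at or above
    ``activity_threshold`` and (b) a new activation (rising crossing of
    ``upstroke_threshold``) occurs somewhere in every rolling
    ``max_quiet_ms`` window.
    """
    if times[-1] < horizon_ms - 1e-9:
        raise ValueError(
            f"continuation covers only {times[-1]:.0f} ms < {horizon_ms:.0f} ms"
        )
    sel = times <= horizon_ms + 1e-9
    v = vm[sel].reshape(np.count_nonzero(sel), -1)[:, conductive.ravel()]
    t = times[sel]
    active = (v >= activity_threshold).any(axis=1)
    if not active[1:].all():
        return False
    rising = ((v[1:] >= upstroke_threshold) & (v[:-1] < upstroke_threshold)).any(axis=1)
    cross_t = t[1:][rising]
    gaps = np.diff(np.r_[0.0, cross_t, horizon_ms])
    return bool(np.all(gaps <= max_quiet_ms + 1e-9))


def ring_mask(
    geom: TissueGeometry,
    site: tuple[int, int],
    ring_mm: tuple[float, float] = (4.0, 6.0),
) -> np.ndarray:
    """Conductive nodes with geodesic distance in ``ring_mm`` from ``site``."""
    g, idx = _conductive_graph(geom)
    i_site = idx[site]
    if i_site < 0:
        raise ValueError("stimulation site is not on conductive tissue")
    d = dijkstra(g, directed=False, indices=i_site)
    dist_map = np.full(geom.shape, np.inf).ravel()
    dist_map[idx.ravel() >= 0] = d[idx.ravel()[idx.ravel() >= 0]]
    dist_map = dist_map.reshape(geom.shape)
    mask = (dist_map >= ring_mm[0]) & (dist_map <= ring_mm[1])
    if not mask.any():
        raise ValueError(
            f"empty propagation ring {ring_mm} mm around site {site}"
        )
    return mask


def propagation_check_movie(
    vm: np.ndarray,
    times: np.ndarray,
    ring: np.ndarray,
    threshold_mv: float = -50.0,
    window_ms: float = 80.0,
) -> bool:
    """True iff a new depolarization reaches the ring within the window.

    A new wave is a *rising* crossing of ``threshold_mv`` at some ring node
    after stimulus onset (movie frame 0 = onset); ring tissue still
    depolarized from the previous activation does not count.
    """
    sel = times <= window_ms + 1e-9
    v = vm[sel][:, ring]
    rising = (v[1:] >= threshold_mv) & (v[:-1] < threshold_mv)
    return bool(rising.any())


def new_wave_check(
    vm: np.ndarray,
    vm_ref: np.ndarray,
    times: np.ndarray,
    ring: np.ndarray,
    threshold_mv: float = -50.0,
    window_ms: float = 80.0,
    earlier_by_ms: float = 10.0,
) -> bool:
    """Ring propagation attributable to the stimulus itself.

    Compares the stimulated movie against a paired reference without the
    stimulus (both starting from the same state at stimulus onset).  True
    iff some ring node shows a rising ``threshold_mv`` crossing that is
    absent in the reference, or occurs at least ``earlier_by_ms`` earlier
    than the reference crossing at that node.
    """
    sel = times <= window_ms + 1e-9
    t = times[sel]

    def first_cross(movie: np.ndarray) -> np.ndarray:
        v = movie[sel][:, ring]
        rising = (v[1:] >= threshold_mv) & (v[:-1] < threshold_mv)
        any_c = rising.any(axis=0)
        idx = rising.argmax(axis=0)
        return np.where(any_c, t[1:][idx], np.inf)

    tc = first_cross(vm)
    tr = first_cross(vm_ref)
    return bool(np.any(tc < tr - earlier_by_ms) or np.any(np.isfinite(tc) & ~np.isfinite(tr)))


# ---------------------------------------------------------------------------
# monodomain backend


class MonodomainBackend:
    """Protocol backend running the monodomain tissue model.

    Beat delivery simulates an observation window after each stimulus to
    evaluate local propagation; the induction check continues the tissue
    for 1.5 s from the current state and rolls back.  All trial/checkpoint
    bookkeeping uses full state copies (cheap at desk scale).
    """

    def __init__(
        self,
        geom: TissueGeometry,
        model: ionic.MembraneModel,
        site: tuple[int, int],
        dt: float = 0.02,
        dt_out: float = 1.0,
        stim_amplitude: float = 30.0,
        stim_edge_mm: float = 2.0,
        stim_duration: float = 2.0,
        check_window_ms: float = 80.0,
        ring_mm: tuple[float, float] = (4.0, 6.0),
        prop_threshold_mv: float = -50.0,
        induction_horizon_ms: float = 1500.0,
        initial_state: np.ndarray | None = None,
        node_scales: np.ndarray | None = None,
    ) -> None:
        self.geom = geom
        self.model = model
        self.site = site
        self.dt = dt
        self.dt_out = dt_out
        self.check_window_ms = check_window_ms
        self.induction_horizon_ms = induction_horizon_ms
        self.prop_threshold_mv = prop_threshold_mv
        self.stim = monodomain.StimulusSpec(
            center=geom.node_pos(site),
            amplitude=stim_amplitude,
            edge_mm=stim_edge_mm,
            duration=stim_duration,
        )
        self.stim.node_mask(geom)  # validate early
        self.ring = ring_mask(geom, site, ring_mm)
        self.conductive = geom.conductive_nodes()
        self.node_scales = (
            monodomain.node_scale_map(geom, model)
            if node_scales is None
            else np.asarray(node_scales, float)
        )
        n = geom.n_nodes
        self.state = (
            np.tile(model.rest_state(), (n, 1))
            if initial_state is None
            else np.array(initial_state, float)
        )
        # state exactly at the last stimulus onset (for re-timed beats)
        self._onset_state: np.ndarray | None = None
        self._elapsed_since_onset = 0.0
        self._simulated_ms = 0.0
        self.last_continuation: monodomain.SimulationResult | None = None

    # -- plumbing ----------------------------------------------------------

    @property
    def simulated_ms(self) -> float:
        return self._simulated_ms

    def _advance(
        self, duration: float, stimulate: bool
    ) -> monodomain.SimulationResult:
        stims = []
        if stimulate:
            st = monodomain.StimulusSpec(
                center=self.stim.center,
                amplitude=self.stim.amplitude,
                edge_mm=self.stim.edge_mm,
                duration=min(self.stim.duration, duration),
                onset=0.0,
            )
            stims = [st]
        res = monodomain.run(
            self.geom,
            self.model,
            stims,
            t_end=duration,
            dt=self.dt,
            dt_out=self.dt_out,
            initial_state=self.state,
            node_scales=self.node_scales,
        )
        self.state = res.final_state
        self._simulated_ms += duration
        return res

    def _beat(self, ci: float) -> bool:
        """Advance to the next onset and stimulate; returns propagation."""
        if self._onset_state is None:
            if ci > 0:
                self._advance(ci, stimulate=False)
        elif ci < self._elapsed_since_onset - 1e-9:
            # earlier than the already-simulated observation window: rewind
            # to the previous onset and replay that beat's stimulus for the
            # (short) coupling before delivering the new one
            self.state = self._onset_state.copy()
            self._advance(max(ci, self.dt), stimulate=True)
        else:
            wait = ci - self._elapsed_since_onset
            if wait > 1e-9:
                self._advance(wait, stimulate=False)
        self._onset_state = self.state.copy()
        self._elapsed_since_onset = self.check_window_ms
        pre = self.state.copy()
        res = self._advance(self.check_window_ms, stimulate=True)
        # paired reference without the new stimulus: ring crossings caused
        # by waves already under way appear identically in both movies and
        # must not count as propagation of the new beat
        ref = monodomain.run(
            self.geom,
            self.model,
            [],
            t_end=self.check_window_ms,
            dt=self.dt,
            dt_out=self.dt_out,
            initial_state=pre,
            node_scales=self.node_scales,
        )
        self._simulated_ms += self.check_window_ms
        flat = res.vm.reshape(res.vm.shape[0], -1)
        flat_ref = ref.vm.reshape(ref.vm.shape[0], -1)
        return new_wave_check(
            flat,
            flat_ref,
            res.times,
            self.ring.ravel(),
            self.prop_threshold_mv,
            self.check_window_ms,
        )

    # -- backend interface -------------------------------------------------

    def deliver_beat(self, ci: float) -> bool:
        return self._beat(ci)

    def trial_beat(self, ci: float) -> bool:
        snap = (
            self.state.copy(),
            None if self._onset_state is None else self._onset_state.copy(),
            self._elapsed_since_onset,
        )
        try:
            return self._beat(ci)
        finally:
            self.state, self._onset_state, self._elapsed_since_onset = snap

    def check_induction(self) -> bool:
        snap = self.state.copy()
        elapsed = self._elapsed_since_onset
        res = self._advance(self.induction_horizon_ms, stimulate=False)
        flat = res.vm.reshape(res.vm.shape[0], -1)
        ok = sustained_activity(
            flat,
            res.times,
            self.conductive,
            horizon_ms=self.induction_horizon_ms,
        )
        self.last_continuation = res
        if not ok:
            self.state = snap
            self._elapsed_since_onset = elapsed
        return ok
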