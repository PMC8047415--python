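"""Phase maps, phase-singularity detection/tracking, episode classification.

The instantaneous phase is obtained by time-delay embedding,
``phi = atan2(Vm(t) - V*, Vm(t - tau) - V*)`` with delay ``tau`` (default
10 ms) and per-node origin ``V*`` (default: the node's mean Vm over the
analysis window).  Phase singularities are plaquette defects: the wrapped
phase circulation around each elementary grid cell equals ±2pi at a PS
(topological charge ±1).  Detections are linked frame-to-frame by greedy
nearest-neighbor association among same-charge PSs within a speed gate.

Episode taxonomy follows the long-living-PS (llPS) scheme: a PS trajectory
is an llPS when it survives >= 500 ms, and *stable* when an llPS spans the
final 1.5 s with its path confined to a bounding box of 5 cm edge.
Induced episodes without any llPS are split into flutter (Fl, periodic
activation with few simultaneous wavefronts) and multiple wavefronts
(Multi) by an explicit heuristic replacing visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhaseParams",
    "PSTrajectory",
    "EpisodeClass",
    "compute_phase",
    "detect_ps",
    "track_ps",
    "classify_llps",
    "classify_episode",
]


@dataclass
class PhaseParams:
    """Time-delay embedding parameters."""

    tau_ms: float = 10.0
    v_star: float | None = None        # None: per-node mean over the window
    min_range_mv: float = 1.0          # nodes with less Vm excursion are masked


@dataclass
class PSTrajectory:
    """Tracked phase-singularity core path."""

    charge: int
    t: list[float] = field(default_factory=list)       # ms
    x: list[float] = field(default_factory=list)       # mm
    y: list[float] = field(default_factory=list)       # mm

    @property
    def lifetime(self) -> float:
        return self.t[-1] - self.t[0] if self.t else 0.0

    def bbox_edge(self, t_lo: float = -np.inf, t_hi: float = np.inf) -> float:
        """Edge of the smallest axis-aligned square covering the path
        within [t_lo, t_hi], mm."""
        sel = [k for k, tk in enumerate(self.t) if t_lo <= tk <= t_hi]
        if not sel:
            return 0.0
        xs = np.array(self.x)[sel]
        ys = np.array(self.y)[sel]
        return float(max(np.ptp(xs), np.ptp(ys)))

    def path_center(self, t_lo: float = -np.inf, t_hi: float = np.inf) -> tuple[float, float]:
        sel = [k for k, tk in enumerate(self.t) if t_lo <= tk <= t_hi]
        if not sel:
            sel = list(range(len(self.t)))
        return (float(np.mean(np.array(self.x)[sel])), float(np.mean(np.array(self.y)[sel])))


@dataclass
class EpisodeClass:
    """Outcome of episode classification with supporting metrics."""

    label: str                          # none|Multi|Fl|nonstable_llPS|stable_llPS
    n_llps: int = 0
    n_stable: int = 0
    cycle_length_ms: float | None = None
    cycle_cv: float | None = None
    mean_wavefronts: float | None = None


# ---------------------------------------------------------------------------


def compute_phase(
    vm: np.ndarray, frame_dt: float, params: PhaseParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time-delay-embedding phase of a Vm movie.

    Parameters
    ----------
    vm : (frames, ny, nx) movie in mV.
    frame_dt : frame interval, ms; the delay must be a multiple of it.

    Returns
    -------
    phase : (frames - lag, ny, nx) in (-pi, pi]; NaN where masked.
    valid : (ny, nx) node mask (False for quiescent / constant nodes).
    """
    params = params or PhaseParams()
    lag_f = params.tau_ms / frame_dt
    if abs(lag_f - round(lag_f)) > 1e-9 or round(lag_f) < 1:
        raise ValueError(
            f"delay {params.tau_ms} ms must be a positive multiple of the "
            f"frame interval {frame_dt} ms"
        )
    lag = int(round(lag_f))
    if vm.shape[0] <= lag:
        raise ValueError("movie shorter than the embedding delay")
    v = vm.astype(np.float64)
    vstar = (
        v.mean(axis=0) if params.v_star is None else np.full(v.shape[1:], params.v_star)
    )
    valid = np.ptp(v, axis=0) >= params.min_range_mv
    phase = np.arctan2(v[lag:] - vstar, v[:-lag] - vstar)
    phase[:, ~valid] = np.nan
    return phase, valid


def _wrap(dphi: np.ndarray) -> np.ndarray:
    return np.mod(dphi + np.pi, 2 * np.pi) - np.pi


def detect_ps(
    phase_frame: np.ndarray, h: float = 1.0, exclude_boundary: bool = True
) -> list[tuple[float, float, int]]:
    """Phase singularities in one phase frame.

    Returns a list of ``(x_mm, y_mm, charge)`` at plaquette centers where
    the wrapped phase circulation is ±2pi.  Plaquettes touching the domain
    boundary or masked nodes are skipped.
    """
    p = phase_frame
    ny, nx = p.shape
    if ny < 2 or nx < 2:
        return []
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, 1:]
    d = p[1:, :-1]
    circ = _wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)
    ok = np.isfinite(circ)
    charge = np.zeros_like(circ)
    charge[ok] = np.round(circ[ok] / (2 * np.pi))
    if exclude_boundary and ny > 2 and nx > 2:
        charge[0, :] = 0
        charge[-1, :] = 0
        charge[:, 0] = 0
        charge[:, -1] = 0
    out = []
    for i, j in zip(*np.nonzero(charge)):
        out.append(((j + 0.5) * h, (i + 0.5) * h, int(charge[i, j])))
    return out


def track_ps(
    detections: list[list[tuple[float, float, int]]],
    times: np.ndarray,
    v_max: float = 1.0,
    gap_bridge: int = 0,
) -> list[PSTrajectory]:
    """Link per-frame PS detections into trajectories.

    Greedy nearest-neighbor frame-to-frame association restricted to
    same-charge detections within ``v_max * dt`` mm (ties broken by
    distance then detection index — deterministic).  A trajectory not
    matched for more than ``gap_bridge`` consecutive frames is closed.
    """
    open_tracks: list[tuple[PSTrajectory, int]] = []  # (traj, frames since seen)
    closed: list[PSTrajectory] = []
    prev_t = None
    for f, dets in enumerate(detections):
        t = float(times[f])
        gate = v_max * (t - prev_t) if prev_t is not None else 0.0
        pairs = []
        for ti, (track, _age) in enumerate(open_tracks):
            for di, (x, y, q) in enumerate(dets):
                if q != track.charge:
                    continue
                dist = np.hypot(x - track.x[-1], y - track.y[-1])
                if dist <= gate + 1e-12:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            track = open_tracks[ti][0]
            x, y, _q = dets[di]
            track.t.append(t)
            track.x.append(x)
            track.y.append(y)
        next_open: list[tuple[PSTrajectory, int]] = []
        for ti, (track, age) in enumerate(open_tracks):
            if ti in used_t:
                next_open.append((track, 0))
            elif age < gap_bridge:
                next_open.append((track, age + 1))
            else:
                closed.append(track)
        for di, (x, y, q) in enumerate(dets):
            if di not in used_d:
                next_open.append((PSTrajectory(charge=q, t=[t], x=[x], y=[y]), 0))
        open_tracks = next_open
        prev_t = t
    closed.extend(tr for tr, _age in open_tracks)
    return closed


def classify_llps(
    traj: PSTrajectory,
    now_ms: float,
    llps_min_ms: float = 500.0,
    stable_window_ms: float = 1500.0,
    bbox_max_mm: float = 50.0,
) -> str:
    """Classify one trajectory: not_llPS, nonstable_llPS or stable_llPS.

    llPS: lifetime >= 500 ms.  Stable: the trajectory spans the whole
    final ``stable_window_ms`` before ``now_ms`` and its path in that
    window fits in an axis-aligned square of edge <= ``bbox_max_mm``.
    """
    if not traj.t:
        raise ValueError("empty trajectory")
    if traj.lifetime < llps_min_ms:
        return "not_llPS"
    t_lo = now_ms - stable_window_ms
    spans = traj.t[0] <= t_lo + 1e-9 and traj.t[-1] >= now_ms - 1e-9
    if spans and traj.bbox_edge(t_lo, now_ms) <= bbox_max_mm + 1e-9:
        return "stable_llPS"
    return "nonstable_llPS"


def _wavefront_count(
    vm: np.ndarray, threshold: float = -40.0, stride: int = 10
) -> float:
    """Mean number of connected wavefront components.

    Upward ``threshold`` crossings are pooled over windows of ``stride``
    frames (a front moving slower than one grid cell per frame would
    otherwise fragment) and 8-connected components are counted per window.
    """
    rising = (vm[1:] >= threshold) & (vm[:-1] < threshold)
    counts = []
    structure = np.ones((3, 3), dtype=int)
    for k in range(0, rising.shape[0] - stride + 1, stride):
        frame = rising[k : k + stride].any(axis=0)
        if frame.any():
            _lbl, n = ndimage.label(frame, structure=structure)
            counts.append(n)
    return float(np.mean(counts)) if counts else 0.0


def _cycle_stats(
    vm: np.ndarray, times: np.ndarray, threshold: float = -40.0
) -> tuple[float | None, float | None]:
    """(mean cycle length, coefficient of variation) over per-node
    activation intervals."""
    rising = (vm[1:] >= threshold) & (vm[:-1] < threshold)
    cls = []
    flat = rising.reshape(rising.shape[0], -1)
    t = times[1:]
    for node in range(flat.shape[1]):
        tk = t[flat[:, node]]
        if tk.size >= 2:
            iv = np.diff(tk)
            # drop the node's first interval (induction transient) when a
            # steadier sample exists
            cls.extend(iv[1:] if iv.size >= 2 else iv)
    if len(cls) < 3:
        return None, None
    cls = np.asarray(cls, float)
    return float(cls.mean()), float(cls.std() / cls.mean())


def classify_episode(
    vm: np.ndarray,
    times: np.ndarray,
    trajectories: list[PSTrajectory],
    induced: bool,
    h: float = 1.0,
    cycle_cv_max: float = 0.1,
    max_wavefronts: float = 2.0,
) -> EpisodeClass:
    """Type an induced episode: stable_llPS / nonstable_llPS / Fl / Multi.

    ``vm``/``times`` is the continuation movie the induction check ran on;
    ``now`` for llPS stability is the last frame time.  Non-induced runs
    return class ``none``.
    """
    if not induced:
        return EpisodeClass(label="none")
    now = float(times[-1])
    kinds = [classify_llps(tr, now) for tr in trajectories if tr.t]
    n_llps = sum(k != "not_llPS" for k in kinds)
    n_stable = sum(k == "stable_llPS" for k in kinds)
    # wavefront statistics over the settled part of the episode (the first
    # third carries the induction transient); cycle statistics use the full
    # window with each node's first interval dropped
    i0 = vm.shape[0] // 3
    cl, cv = _cycle_stats(vm, times)
    wf = _wavefront_count(vm[i0:])
    if n_stable:
        label = "stable_llPS"
    elif n_llps:
        label = "nonstable_llPS"
    elif cv is not None and cv < cycle_cv_max and wf <= max_wavefronts:
        label = "Fl"
    else:
        label = "Multi"
    return EpisodeClass(
        label=label,
        n_llps=n_llps,
        n_stable=n_stable,
        cycle_length_ms=cl,
        cycle_cv=cv,
        mean_wavefronts=wf,
    )
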