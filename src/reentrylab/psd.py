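"""Phase-singularity-distribution (PSD) reentry initialization.

Seeds a single spiral wave: an activation-time map is built around a chosen
core as ``T(x) = mod(CL * theta(x) / 2pi + D(x) / v, CL)`` where ``theta``
is the angle around the core (sign set by the requested chirality), ``D``
the eikonal (fast-marching) distance from the core through conductive
tissue and ``v`` the conduction speed.  The map is converted into a full
tissue state by sampling a steady-pacing limit-cycle trajectory at phase
``mod(-T(x), CL)`` per node, and the monodomain solver continues from
there.

The re-entry cycle length follows the 5%-above-ERP rule (e.g. ERP 300 ms
-> CL 315 ms for the control membrane, ERP 160 ms -> 168 ms for the
chronic-AF variant).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .geometry import TissueGeometry

__all__ = [
    "PSDParams",
    "psd_cycle_length",
    "fast_marching_distance",
    "spiral_activation_map",
    "map_to_state",
]


@dataclass
class PSDParams:
    """Spiral-seeding parameters."""

    ps_location: tuple[float, float]        # (x, y) mm
    cl: float                               # cycle length, ms
    speed: float                            # eikonal conduction speed, m/s
    chirality: str = "anticlockwise"

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ValueError("cycle length must be positive")
        if self.speed <= 0:
            raise ValueError("conduction speed must be positive")
        if self.chirality not in ("anticlockwise", "clockwise"):
            raise ValueError(f"unknown chirality {self.chirality!r}")


def psd_cycle_length(erp: float) -> float:
    """Reentry cycle length: 5% longer than the ERP, rounded to nearest ms."""
    if erp < 0:
        raise ValueError(f"ERP must be non-negative, got {erp}")
    return float(round(1.05 * erp))


def fast_marching_distance(
    geom: TissueGeometry, source: tuple[float, float]
) -> np.ndarray:
    """First-order fast-marching distance (mm) from ``source`` through
    conductive tissue; nonconductive nodes get +inf."""
    cond = geom.conductive_nodes()
    ny, nx = cond.shape
    h = geom.h
    si, sj = geom.nearest_node(source)
    if not cond[si, sj]:
        raise ValueError("source lies on nonconductive tissue")
    INF = np.inf
    dist = np.full((ny, nx), INF)
    done = np.zeros((ny, nx), dtype=bool)
    dist[si, sj] = 0.0
    heap: list[tuple[float, int, int]] = [(0.0, si, sj)]
    while heap:
        d, i, j = heapq.heappop(heap)
        if done[i, j]:
            continue
        done[i, j] = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if not (0 <= ii < ny and 0 <= jj < nx):
                continue
            if done[ii, jj] or not cond[ii, jj]:
                continue
            # upwind neighbors of the candidate node
            a = min(
                dist[ii, jj - 1] if jj > 0 else INF,
                dist[ii, jj + 1] if jj < nx - 1 else INF,
            )
            b = min(
                dist[ii - 1, jj] if ii > 0 else INF,
                dist[ii + 1, jj] if ii < ny - 1 else INF,
            )
            if a > b:
                a, b = b, a
            if b - a >= h or not np.isfinite(b):
                cand = a + h
            else:
                cand = 0.5 * (a + b + np.sqrt(2 * h * h - (b - a) ** 2))
            if cand < dist[ii, jj]:
                dist[ii, jj] = cand
                heapq.heappush(heap, (cand, ii, jj))
    return dist


def spiral_activation_map(geom: TissueGeometry, params: PSDParams) -> np.ndarray:
    """CL-periodic activation-time map (ms) with one phase singularity.

    Values lie in ``[0, CL)``.  Anticlockwise chirality corresponds to
    positive winding in the standard planar orientation (x right, y up).
    Nonconductive nodes get NaN.
    """
    x, y = geom.node_positions()
    cx, cy = params.ps_location
    theta = np.arctan2(y - cy, x - cx)
    if params.chirality == "clockwise":
        theta = -theta
    d = fast_marching_distance(geom, params.ps_location)
    v = params.speed  # m/s == mm/ms
    t = np.mod(params.cl * theta / (2 * np.pi) + d / v, params.cl)
    t[~np.isfinite(d)] = np.nan
    return t


def map_to_state(
    geom: TissueGeometry,
    model,
    tmap: np.ndarray,
    template: np.ndarray,
    cl: float,
) -> np.ndarray:
    """Convert an activation-time map into a tissue state array.

    ``template`` is a limit-cycle trajectory ``(n_frames, n_states)``
    covering one period ``cl`` starting at the upstroke (see
    :func:`reentrylab.ionic.limit_cycle_template`).  Node ``x`` receives the
    template state at elapsed phase ``mod(-T(x), cl)``; nonconductive /
    unreachable nodes are set to rest.
    """
    n_frames = template.shape[0]
    if abs(n_frames * (cl / n_frames) - cl) > 1e-9 or not (
        0.5 * cl <= n_frames <= 2.0 * cl + 1
    ):
        raise ValueError(
            f"template with {n_frames} frames does not cover cycle length "
            f"{cl} ms at a ~1 ms sampling"
        )
    frame_dt = cl / n_frames
    bad = ~np.isfinite(tmap.ravel())
    phase = np.mod(-np.nan_to_num(tmap), cl)
    flat_idx = (np.round(phase / frame_dt).astype(np.int64) % n_frames).ravel()
    flat_idx[bad] = 0
    state = template[flat_idx].astype(np.float64)
    state[bad] = model.rest_state()
    return state
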