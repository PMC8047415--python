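"""Monodomain reaction-diffusion tissue solver.

Operator-split explicit scheme: a 5-point (3-point in 1D) finite-difference
diffusion step with harmonic-mean face conductivities and no-flux
boundaries, followed by the ionic reaction step (Rush-Larsen / forward
Euler), at a default time step of 0.02 ms.  Nonconductive elements stay in
the grid with sigma = 1e-7 S/m and act as passive barriers.

The transmembrane stimulus is a current density over a square footprint
(default 30 uA/cm^2 over 2 x 2 mm for 2 ms); with the membrane capacitance
of 1 uF/cm^2 this equals 30 pA/pF in the ionic equation.

Monodomain diffusivity D = sigma / (beta * C_m) with surface-to-volume
ratio beta = 0.14 um^-1 and C_m = 1 uF/cm^2 (values from the cited membrane
model's conventions; both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import ionic
from .geometry import FIBROTIC_REMODELED, TissueGeometry

__all__ = [
    "StimulusSpec",
    "SimulationResult",
    "SolverError",
    "run",
    "measure_cv",
    "tune_conductivity",
    "BETA_PER_M",
    "CM_F_PER_M2",
    "diffusivity_mm2_per_ms",
]

#: surface-to-volume ratio, 1/m (0.14 um^-1)
BETA_PER_M = 0.14e6
#: specific membrane capacitance, F/m^2 (1 uF/cm^2)
CM_F_PER_M2 = 0.01


def diffusivity_mm2_per_ms(sigma_s_per_m: np.ndarray | float) -> np.ndarray | float:
    """Monodomain diffusivity D = sigma/(beta*Cm), converted to mm^2/ms."""
    return sigma_s_per_m / (BETA_PER_M * CM_F_PER_M2) * 1e3


class SolverError(RuntimeError):
    """Numerical failure (instability or non-finite state)."""


@dataclass
class StimulusSpec:
    """Square transmembrane-current stimulus footprint."""

    center: tuple[float, float]            # (x, y) mm
    amplitude: float = 30.0                # uA/cm^2 == pA/pF
    edge_mm: float = 2.0
    duration: float = 2.0                  # ms
    onset: float = 0.0                     # ms

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("stimulus amplitude must be positive")

    def node_mask(self, geom: TissueGeometry) -> np.ndarray:
        """Boolean (ny, nx) mask of conductive nodes inside the footprint."""
        x, y = geom.node_positions()
        cx, cy = self.center
        half = self.edge_mm / 2
        inside = (np.abs(x - cx) <= half + 1e-9) & (np.abs(y - cy) <= half + 1e-9)
        mask = inside & geom.conductive_nodes()
        if not mask.any():
            raise ValueError(
                f"stimulus at {self.center} mm covers no conductive node"
            )
        return mask


@dataclass
class SimulationResult:
    """Vm movie plus final full state of a monodomain run."""

    vm: np.ndarray                 # (frames, ny, nx) mV, float32
    times: np.ndarray              # (frames,) ms
    dt: float
    dt_out: float
    final_state: np.ndarray        # (n_nodes, n_states)
    geom: TissueGeometry
    stimuli: list[StimulusSpec] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.vm.shape[0]

    def activation_times(
        self, threshold: float = -40.0, after: float = 0.0
    ) -> np.ndarray:
        """First rising crossing of ``threshold`` per node, ms; NaN if never.

        ``after`` restricts the search to frames at t >= after.
        """
        i0 = int(np.searchsorted(self.times, after))
        vm = self.vm[i0:]
        if vm.shape[0] < 2:
            return np.full(self.vm.shape[1:], np.nan)
        rising = (vm[1:] >= threshold) & (vm[:-1] < threshold)
        any_cross = rising.any(axis=0)
        first = rising.argmax(axis=0)
        at = np.where(any_cross, self.times[i0:][first + 1], np.nan)
        return at


# ---------------------------------------------------------------------------
# face diffusion coefficients


def _face_coefficients(geom: TissueGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(Dx, Dy) face diffusivities in mm^2/ms.

    Dx has shape (ny, nx-1) (faces between horizontal node neighbors), Dy
    shape (ny-1, nx).  Each face takes the harmonic mean of the
    conductivities of the two elements flanking it (the single flanking
    element on domain boundaries).
    """
    sig = geom.sigma
    ny, nx = geom.shape
    if geom.ny == 1:
        dx = diffusivity_mm2_per_ms(sig[0]).reshape(1, -1)
        return dx, np.zeros((0, nx))
    # horizontal face (i, j)-(i, j+1): flanking elements rows i-1 and i, col j
    above = sig[np.clip(np.arange(ny) - 1, 0, ny - 2)][:, :]
    below = sig[np.clip(np.arange(ny), 0, ny - 2)][:, :]
    dx_sig = _harmonic(above, below)
    dx_sig[0] = sig[0]
    dx_sig[-1] = sig[-1]
    # vertical face (i, j)-(i+1, j): flanking elements cols j-1 and j, row i
    left = sig[:, np.clip(np.arange(nx) - 1, 0, nx - 2)]
    right = sig[:, np.clip(np.arange(nx), 0, nx - 2)]
    dy_sig = _harmonic(left, right)
    dy_sig[:, 0] = sig[:, 0]
    dy_sig[:, -1] = sig[:, -1]
    return diffusivity_mm2_per_ms(dx_sig), diffusivity_mm2_per_ms(dy_sig)


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def node_scale_map(geom: TissueGeometry, model: ionic.MembraneModel) -> np.ndarray:
    """Per-node conductance scales (n_nodes, 7).

    Nodes touching at least one fibrotic-remodeled element get the cytokine
    conductance rescaling (-50% g_K1, -40% g_Na, -50% g_CaL) on top of the
    model's own scales.
    """
    base = model.scale_vector()
    ny, nx = geom.shape
    sc = np.tile(base, (ny * nx, 1))
    remod_el = geom.labels == FIBROTIC_REMODELED
    if remod_el.any():
        mask = np.zeros((ny, nx), dtype=bool)
        if ny == 1:
            mask[0, :-1] |= remod_el[0]
            mask[0, 1:] |= remod_el[0]
        else:
            mask[:-1, :-1] |= remod_el
            mask[:-1, 1:] |= remod_el
            mask[1:, :-1] |= remod_el
            mask[1:, 1:] |= remod_el
        cyt = ionic.apply_remodeling(
            model, ionic.CYTOKINE_FIBROTIC
        ).scale_vector()
        sc[mask.ravel()] = cyt
    return sc


# ---------------------------------------------------------------------------
# jitted tissue drivers


@njit(cache=True)
def _diffuse(vm, dx, dy, coef, ny, nx, out):
    for i in range(ny):
        for j in range(nx):
            acc = 0.0
            v = vm[i, j]
            if j > 0:
                acc += dx[i, j - 1] * (vm[i, j - 1] - v)
            if j < nx - 1:
                acc += dx[i, j] * (vm[i, j + 1] - v)
            if ny > 1:
                if i > 0:
                    acc += dy[i - 1, j] * (vm[i - 1, j] - v)
                if i < ny - 1:
                    acc += dy[i, j] * (vm[i + 1, j] - v)
            out[i, j] = v + coef * acc


@njit(cache=True)
def _tissue_run_crn(S, istim, dt, n_steps, sc, dx, dy, coef, ny, nx, rec, k, stride, step0):
    vm = np.empty((ny, nx))
    for step in range(n_steps):
        vmf = S[:, 0].copy().reshape(ny, nx)
        _diffuse(vmf, dx, dy, coef, ny, nx, vm)
        S[:, 0] = vm.ravel()
        _crn_step(S, istim, dt, sc)
        gs = step0 + step + 1
        if gs % stride == 0:
            rec[k] = S[:, 0].astype(np.float32).reshape(ny, nx)
            k += 1
    return k


@njit(cache=True)
def _tissue_run_fk(S, istim, dt, n_steps, sc, dx, dy, coef, ny, nx, rec, k, stride, step0):
    vm = np.empty((ny, nx))
    for step in range(n_steps):
        vmf = S[:, 0].copy().reshape(ny, nx)
        _diffuse(vmf, dx, dy, coef, ny, nx, vm)
        S[:, 0] = vm.ravel()
        _fk_step(S, istim, dt, sc)
        gs = step0 + step + 1
        if gs % stride == 0:
            rec[k] = S[:, 0].astype(np.float32).reshape(ny, nx)
            k += 1
    return k


# re-export the jitted ionic kernels into this namespace for the drivers
_crn_step = ionic._crn_step
_fk_step = ionic._fk_step


# ---------------------------------------------------------------------------
# main entry


def run(
    geom: TissueGeometry,
    model: ionic.MembraneModel,
    stimuli: list[StimulusSpec],
    t_end: float,
    dt: float = 0.02,
    dt_out: float = 1.0,
    initial_state: np.ndarray | None = None,
    node_scales: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the monodomain system on ``geom`` for ``t_end`` ms.

    Raises :class:`SolverError` on numerical instability (|Vm| > 200 mV or
    non-finite state) and ``ValueError`` if the explicit-diffusion stability
    bound is violated.
    """
    ny, nx = geom.shape
    n = ny * nx
    dx, dy = _face_coefficients(geom)
    dmax = max(dx.max(), dy.max() if dy.size else 0.0)
    axes = 2 if ny > 1 else 1
    if dt * dmax * 2 * axes / geom.h**2 > 1.0:
        raise ValueError(
            f"explicit diffusion unstable: dt={dt} ms, D={dmax:.3g} mm^2/ms, "
            f"h={geom.h} mm; need dt <= {geom.h ** 2 / (2 * axes * dmax):.4f} ms"
        )
    if model.name == "courtemanche" and dt > 0.05:
        raise ValueError(f"courtemanche requires dt <= 0.05 ms, got {dt}")

    if initial_state is None:
        S = np.tile(model.rest_state(), (n, 1))
    else:
        S = np.array(initial_state, dtype=np.float64)
        if S.shape != (n, model.n_states):
            raise ValueError(
                f"initial state shape {S.shape} != {(n, model.n_states)}"
            )
    sc = node_scale_map(geom, model) if node_scales is None else node_scales

    for st in stimuli:
        st.node_mask(geom)  # validates footprint

    n_steps = int(round(t_end / dt))
    stride = max(1, int(round(dt_out / dt)))
    n_rec = n_steps // stride + 1
    rec = np.empty((n_rec, ny, nx), dtype=np.float32)
    rec[0] = S[:, 0].reshape(ny, nx).astype(np.float32)
    k = 1

    # segment the timeline at stimulus on/off edges
    edges = {0, n_steps}
    for st in stimuli:
        edges.add(int(round(st.onset / dt)))
        edges.add(int(round((st.onset + st.duration) / dt)))
    bounds = sorted(e for e in edges if 0 <= e <= n_steps)

    runner = _tissue_run_crn if model.name == "courtemanche" else _tissue_run_fk
    coef = dt / geom.h**2
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 == b0:
            continue
        t_mid = (b0 + 0.5) * dt
        istim = np.zeros(n)
        for st in stimuli:
            if st.onset <= t_mid < st.onset + st.duration:
                istim[st.node_mask(geom).ravel()] += st.amplitude
        k = runner(S, istim, dt, b1 - b0, sc, dx, dy, coef, ny, nx, rec, k, stride, b0)
        vmax = np.abs(S[:, 0]).max()
        if not np.isfinite(vmax) or vmax > 200.0:
            raise SolverError(
                f"instability at t = {b1 * dt:.2f} ms: max |Vm| = {vmax:.3g} mV"
            )

    times = np.arange(k) * stride * dt
    return SimulationResult(
        vm=rec[:k], times=times, dt=dt, dt_out=dt_out, final_state=S,
        geom=geom, stimuli=list(stimuli),
    )


# ---------------------------------------------------------------------------
# conduction velocity


def measure_cv(
    result: SimulationResult,
    window: tuple[float, float] | None = None,
    axis: str = "x",
    threshold: float = -40.0,
) -> float:
    """Conduction velocity (m/s) from activation-time regression.

    ``window`` is the (lo, hi) position range in mm along ``axis`` over
    which the regression runs (default: central 60% of the domain).  For 2D
    results the activation times are averaged across the transverse axis
    (planar-wave assumption).  Non-monotone activation along the axis is
    rejected.
    """
    at = result.activation_times(threshold)
    geom = result.geom
    if axis == "x":
        profile = at.mean(axis=0) if at.ndim == 2 else at
        pos = np.arange(geom.nx) * geom.h
    else:
        profile = at.mean(axis=1)
        pos = np.arange(geom.ny) * geom.h
    lo, hi = window if window is not None else (0.2 * pos[-1], 0.8 * pos[-1])
    lo, hi = min(lo, hi), max(lo, hi)
    sel = (pos >= lo) & (pos <= hi)
    t_sel, p_sel = profile[sel], pos[sel]
    if np.any(~np.isfinite(t_sel)):
        raise ValueError("window contains never-activated nodes")
    order = np.diff(t_sel)
    if not (np.all(order >= 0) or np.all(order <= 0)):
        raise ValueError("non-monotone activation in window (reentry/curvature?)")
    if np.ptp(t_sel) == 0:
        raise ValueError("no activation-time gradient in window")
    slope = np.polyfit(t_sel, p_sel, 1)[0]  # mm/ms == m/s
    return float(abs(slope))


def tune_conductivity(
    target_cv: float,
    model: ionic.MembraneModel,
    h: float = 0.25,
    length_mm: float = 50.0,
    dt: float = 0.02,
    tol: float = 0.01,
    bracket: tuple[float, float] = (0.05, 1.2),
    max_expand: int = 6,
    max_iter: int = 40,
) -> tuple[float, float]:
    """Bisect on bulk conductivity until a strand's CV matches ``target_cv``.

    Returns ``(sigma_s_per_m, achieved_cv)``.  The CV is measured by
    activation-time regression over the central 3 cm of a ``length_mm``
    strand paced from one end.  Raises ``ValueError`` if the target cannot
    be bracketed after geometric expansion of the search interval.
    """
    from .geometry import make_strand

    def cv_of(sigma: float) -> float:
        geom = make_strand(int(round(length_mm / h)) + 1, h, sigma=sigma)
        stim = StimulusSpec(center=(0.0, 0.0), onset=1.0)
        t_end = length_mm / 0.15 + 50.0  # slowest bracketable CV ~0.15 m/s
        res = run(geom, model, [stim], t_end=t_end, dt=dt)
        mid = length_mm / 2
        return measure_cv(res, window=(mid - 15.0, mid + 15.0))

    def safe_cv(sigma: float) -> float | None:
        """None when the strand fails to propagate or the scheme cannot
        run stably at this conductivity."""
        try:
            return cv_of(sigma)
        except ValueError:
            return None

    lo, hi = bracket
    cv_lo = safe_cv(lo) or 0.0
    cv_hi = safe_cv(hi)
    for _ in range(max_expand):
        if cv_hi is not None and cv_lo <= target_cv <= cv_hi:
            break
        if cv_hi is not None and target_cv < cv_lo:
            lo /= 2.0
            cv_lo = safe_cv(lo) or 0.0
        else:
            nxt = hi * 2.0
            v = safe_cv(nxt)
            if v is None:
                break  # cannot push the scheme further up
            hi, cv_hi = nxt, v
    if cv_hi is None or not (cv_lo <= target_cv <= cv_hi):
        raise ValueError(
            f"target CV {target_cv} m/s not bracketable; achieved range "
            f"[{cv_lo:.3f}, {cv_hi if cv_hi is not None else float('nan'):.3f}] "
            f"m/s for sigma in [{lo:.4g}, {hi:.4g}] S/m"
        )
    sigma, cv = (lo + hi) / 2, np.nan
    for _ in range(max_iter):
        sigma = (lo + hi) / 2
        cv = safe_cv(sigma)
        if cv is None:
            cv = 0.0
        if abs(cv - target_cv) <= tol:
            return sigma, cv
        if cv < target_cv:
            lo = sigma
        else:
            hi = sigma
    return sigma, cv
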