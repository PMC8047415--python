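"""Membrane kinetics: human atrial ionic models and single-cell utilities.

Two membrane models are provided:

* ``courtemanche`` — the Courtemanche–Ramirez–Nattel human atrial myocyte
  model (21 state variables), the physiological workhorse.  Remodeling
  presets rescale maximal conductances: the cytokine-fibrotic preset is
  fixed to {g_K1: 0.5, g_Na: 0.6, g_CaL: 0.5}; a chronic-AF preset with
  configurable factors is provided for AF-remodeled substrate.
* ``fast_test`` — a three-variable phenomenological model (Fenton–Karma
  family: fast inward, slow outward, slow inward currents) that supports
  propagating pulses and spiral re-entry at a fraction of the cost; used
  where full ionic detail is not required.

Integration is hybrid Rush–Larsen (exponential update for gates) plus
forward Euler for voltage and concentrations, default dt = 0.02 ms.
Kernels are numba-compiled and operate on ``(n_cells, n_states)`` arrays so
the same code serves single cells and tissue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "MembraneModel",
    "RemodelingPreset",
    "IntegrationError",
    "courtemanche_model",
    "fast_test_model",
    "get_model",
    "apply_remodeling",
    "step_cell",
    "simulate_cell",
    "apd94",
    "cell_erp_scan",
    "limit_cycle_template",
    "CRN_N_STATES",
    "FK_N_STATES",
]


class IntegrationError(RuntimeError):
    """Raised when the ionic integration produces non-finite state."""


# conductance-scale vector layout shared by presets and kernels
SCALE_KEYS = ("g_Na", "g_K1", "g_to", "g_Kur", "g_Kr", "g_Ks", "g_CaL")

CRN_N_STATES = 21
FK_N_STATES = 3

# Courtemanche state layout
_V, _M, _H, _J, _OA, _OI, _UA, _UI, _XR, _XS = range(10)
_D, _F, _FCA, _U, _VG, _W, _NAI, _KI, _CAI, _CAUP, _CAREL = range(10, 21)

# canonical resting state of the Courtemanche model
_CRN_REST = np.array(
    [
        -81.18,       # V (mV)
        2.908e-3,     # m
        9.649e-1,     # h
        9.775e-1,     # j
        3.043e-2,     # oa
        9.992e-1,     # oi
        4.966e-3,     # ua
        9.986e-1,     # ui
        3.296e-5,     # xr
        1.869e-2,     # xs
        1.367e-4,     # d
        9.996e-1,     # f
        7.755e-1,     # f_Ca
        0.0,          # u (release activation)
        1.0,          # v (release inactivation)
        9.992e-1,     # w
        1.117e1,      # [Na]_i (mM)
        1.390e2,      # [K]_i (mM)
        1.013e-4,     # [Ca]_i (mM)
        1.488,        # [Ca]_up (mM)
        1.488,        # [Ca]_rel (mM)
    ]
)

# fast_test rest: V (mV), v, w
_FK_REST = np.array([-85.0, 1.0, 1.0])


@dataclass(frozen=True)
class MembraneModel:
    """Ionic model selection plus maximal-conductance scale factors."""

    name: str
    scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.scales.items():
            if k not in SCALE_KEYS:
                raise KeyError(f"unknown conductance key {k!r}; known: {SCALE_KEYS}")
            if v <= 0:
                raise ValueError(f"scale factor for {k} must be positive, got {v}")

    @property
    def n_states(self) -> int:
        return CRN_N_STATES if self.name == "courtemanche" else FK_N_STATES

    def rest_state(self) -> np.ndarray:
        base = _CRN_REST if self.name == "courtemanche" else _FK_REST
        return base.copy()

    def scale_vector(self) -> np.ndarray:
        return np.array([self.scales.get(k, 1.0) for k in SCALE_KEYS])

    def step(self, states: np.ndarray, istim: np.ndarray, dt: float) -> None:
        """Advance ``states`` (n_cells, n_states) in place by one step.

        ``istim`` is the stimulus in pA/pF (equivalently mV/ms), positive
        depolarizing.
        """
        if self.name == "courtemanche":
            if dt > 0.05:
                raise ValueError(f"courtemanche requires dt <= 0.05 ms, got {dt}")
            sc = np.tile(self.scale_vector(), (states.shape[0], 1))
            _crn_step(states, istim, dt, sc)
        elif self.name == "fast_test":
            sc = np.tile(self.scale_vector(), (states.shape[0], 1))
            _fk_step(states, istim, dt, sc)
        else:  # pragma: no cover
            raise ValueError(f"unknown model {self.name!r}")


@dataclass(frozen=True)
class RemodelingPreset:
    """Named maximal-conductance rescaling.

    ``control`` maps everything to 1.0.  ``cytokine_fibrotic`` is the
    cytokine-related remodeling applied in conducting fibrotic tissue
    (-50% g_K1, -40% g_Na, -50% g_CaL).  ``AF`` is a chronic-AF electrical
    remodeling variant (the exact factors are configurable; defaults from
    the widely used chronic-AF adaptation of the same atrial model).
    """

    name: str
    scale_map: dict[str, float]


CONTROL = RemodelingPreset("control", {k: 1.0 for k in SCALE_KEYS})
CYTOKINE_FIBROTIC = RemodelingPreset(
    "cytokine_fibrotic", {"g_K1": 0.5, "g_Na": 0.6, "g_CaL": 0.5}
)
AF = RemodelingPreset(
    "AF", {"g_CaL": 0.3, "g_to": 0.5, "g_Kur": 0.5, "g_K1": 2.0}
)

PRESETS = {p.name: p for p in (CONTROL, CYTOKINE_FIBROTIC, AF)}


def courtemanche_model() -> MembraneModel:
    return MembraneModel("courtemanche")


def fast_test_model() -> MembraneModel:
    return MembraneModel("fast_test")


def get_model(name: str) -> MembraneModel:
    if name in ("courtemanche", "fast_test"):
        return MembraneModel(name)
    raise ValueError(f"unknown membrane model {name!r}")


def apply_remodeling(model: MembraneModel, preset: RemodelingPreset) -> MembraneModel:
    """Multiply the model's conductance scales by the preset's factors."""
    for k, v in preset.scale_map.items():
        if k not in SCALE_KEYS:
            raise KeyError(f"unknown conductance key {k!r}")
        if v <= 0:
            raise ValueError(f"scale factor for {k} must be positive, got {v}")
    merged = dict(model.scales)
    for k, v in preset.scale_map.items():
        merged[k] = merged.get(k, 1.0) * v
    merged = {k: v for k, v in merged.items() if v != 1.0}
    return replace(model, scales=merged)


# ---------------------------------------------------------------------------
# Courtemanche kernel


@njit(cache=True)
def _crn_step(S, istim, dt, sc):  # noqa: C901 - monolithic for speed
    R = 8.3143
    T = 310.0
    F = 96.4867
    RTF = R * T / F
    Cm = 100.0          # pF
    Vi = 13668.0        # um^3
    Vup = 1109.52
    Vrel = 96.48
    Ko = 5.4
    Nao = 140.0
    Cao = 1.8
    gbCa = 0.001131
    gbNa = 0.0006744375
    INaKmax = 0.59933874
    INaCamax = 1600.0
    IpCamax = 0.275
    Iupmax = 0.005
    KQ10 = 3.0
    gamma = 0.35
    KmNai = 10.0
    KmKo = 1.5
    KmNa = 87.5
    KmCa = 1.38
    ksat = 0.1
    krel = 30.0
    kup = 0.00092
    Caupmax = 15.0
    CMDNmax = 0.05
    TRPNmax = 0.07
    CSQNmax = 10.0
    KmCMDN = 0.00238
    KmTRPN = 0.0005
    KmCSQN = 0.8
    tau_tr = 180.0
    tau_fca = 2.0
    tau_u = 8.0

    n = S.shape[0]
    for i in range(n):
        gNa = 7.8 * sc[i, 0]
        gK1 = 0.09 * sc[i, 1]
        gto = 0.1652 * sc[i, 2]
        gKr = 0.029411765 * sc[i, 4]
        gKs = 0.12941176 * sc[i, 5]
        gCaL = 0.12375 * sc[i, 6]
        V = S[i, 0]
        m = S[i, 1]
        h = S[i, 2]
        j = S[i, 3]
        oa = S[i, 4]
        oi = S[i, 5]
        ua = S[i, 6]
        ui = S[i, 7]
        xr = S[i, 8]
        xs = S[i, 9]
        d = S[i, 10]
        f = S[i, 11]
        fca = S[i, 12]
        u = S[i, 13]
        vg = S[i, 14]
        w = S[i, 15]
        Nai = S[i, 16]
        Ki = S[i, 17]
        Cai = S[i, 18]
        Caup = S[i, 19]
        Carel = S[i, 20]

        ENa = RTF * math.log(Nao / Nai)
        EK = RTF * math.log(Ko / Ki)
        ECa = 0.5 * RTF * math.log(Cao / Cai)

        # fast sodium
        INa = gNa * m * m * m * h * j * (V - ENa)
        dv = V + 47.13
        if abs(dv) < 1e-10:
            am = 3.2
        else:
            am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
        bm = 0.08 * math.exp(-V / 11.0)
        if V >= -40.0:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
            aj = 0.0
            bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
        else:
            ah = 0.135 * math.exp(-(V + 80.0) / 6.8)
            bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
            aj = (
                (-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
                * (V + 37.78)
                / (1.0 + math.exp(0.311 * (V + 79.23)))
            )
            bj = 0.1212 * math.exp(-0.01052 * V) / (
                1.0 + math.exp(-0.1378 * (V + 40.14))
            )

        # inward rectifier
        IK1 = gK1 * (V - EK) / (1.0 + math.exp(0.07 * (V + 80.0)))

        # transient outward
        Ito = gto * oa * oa * oa * oi * (V - EK)
        aoa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
        boa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
        tau_oa = 1.0 / ((aoa + boa) * KQ10)
        oa_inf = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
        aoi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
        boi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
        tau_oi = 1.0 / ((aoi + boi) * KQ10)
        oi_inf = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))

        # ultrarapid delayed rectifier
        gKur = sc[i, 3] * (0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0)))
        IKur = gKur * ua * ua * ua * ui * (V - EK)
        aua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
        bua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
        tau_ua = 1.0 / ((aua + bua) * KQ10)
        ua_inf = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
        aui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
        bui = math.exp((V - 158.0) / 16.0)
        tau_ui = 1.0 / ((aui + bui) * KQ10)
        ui_inf = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))

        # rapid delayed rectifier
        IKr = gKr * xr * (V - EK) / (1.0 + math.exp((V + 15.0) / 22.4))
        dv = V + 14.1
        if abs(dv) < 1e-10:
            axr = 0.0015
        else:
            axr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
        dv = V - 3.3328
        if abs(dv) < 1e-10:
            bxr = 7.3898e-5 * 5.1237
        else:
            bxr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
        tau_xr = 1.0 / (axr + bxr)
        xr_inf = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))

        # slow delayed rectifier
        IKs = gKs * xs * xs * (V - EK)
        dv = V - 19.9
        if abs(dv) < 1e-10:
            axs = 4.0e-5 * 17.0
            bxs = 3.5e-5 * 9.0
        else:
            axs = 4.0e-5 * dv / (1.0 - math.exp(-dv / 17.0))
            bxs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
        tau_xs = 0.5 / (axs + bxs)
        xs_inf = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))

        # L-type calcium
        ICaL = gCaL * d * f * fca * (V - 65.0)
        dv = V + 10.0
        if abs(dv) < 1e-10:
            tau_d = 1.0 / (0.035 * 6.24 * 2.0)
        else:
            e = math.exp(-dv / 6.24)
            tau_d = (1.0 - e) / (0.035 * dv * (1.0 + e))
        d_inf = 1.0 / (1.0 + math.exp(-dv / 8.0))
        f_inf = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
        tau_f = 9.0 / (0.0197 * math.exp(-0.0337 * 0.0337 * dv * dv) + 0.02)
        fca_inf = 1.0 / (1.0 + Cai / 0.00035)

        # pumps and exchangers
        sig = (math.exp(Nao / 67.3) - 1.0) / 7.0
        fNaK = 1.0 / (
            1.0
            + 0.1245 * math.exp(-0.1 * V / RTF)
            + 0.0365 * sig * math.exp(-V / RTF)
        )
        INaK = (
            INaKmax
            * fNaK
            / (1.0 + (KmNai / Nai) ** 1.5)
            * Ko
            / (Ko + KmKo)
        )
        expg = math.exp(gamma * V / RTF)
        expg1 = math.exp((gamma - 1.0) * V / RTF)
        INaCa = (
            INaCamax
            * (expg * Nai ** 3 * Cao - expg1 * Nao ** 3 * Cai)
            / (
                (KmNa ** 3 + Nao ** 3)
                * (KmCa + Cao)
                * (1.0 + ksat * expg1)
            )
        )
        IbNa = gbNa * (V - ENa)
        IbCa = gbCa * (V - ECa)
        IpCa = IpCamax * Cai / (0.0005 + Cai)

        # SR calcium handling
        Irel = krel * u * u * vg * w * (Carel - Cai)
        Itr = (Caup - Carel) / tau_tr
        Iup = Iupmax / (1.0 + kup / Cai)
        Iupleak = Iupmax * Caup / Caupmax

        Fn = 1.0e3 * (
            1.0e-15 * Vrel * Irel
            - 1.0e-15 / (2.0 * F) * (0.5 * ICaL - 0.2 * INaCa) * Cm
        )
        u_inf = 1.0 / (1.0 + math.exp(-(Fn - 3.4175e-13) / 13.67e-16))
        v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(Fn - 6.835e-14) / 13.67e-16))
        tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(Fn - 3.4175e-13) / 13.67e-16))
        w_inf = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))
        dv = V - 7.9
        if abs(dv) < 1e-10:
            tau_w = 6.0 / 6.5
        else:
            e = math.exp(-dv / 5.0)
            tau_w = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)

        Iion = (
            INa + IK1 + Ito + IKur + IKr + IKs + ICaL
            + IpCa + INaK + INaCa + IbNa + IbCa
        )

        # concentration updates (currents in pA/pF -> pA via Cm)
        dNai = (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) * Cm / (F * Vi)
        dKi = (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs) * Cm / (F * Vi)
        B1 = (2.0 * INaCa - IpCa - ICaL - IbCa) * Cm / (2.0 * F * Vi) + (
            Vup * (Iupleak - Iup) + Irel * Vrel
        ) / Vi
        B2 = (
            1.0
            + TRPNmax * KmTRPN / ((Cai + KmTRPN) * (Cai + KmTRPN))
            + CMDNmax * KmCMDN / ((Cai + KmCMDN) * (Cai + KmCMDN))
        )
        dCaup = Iup - Iupleak - Itr * Vrel / Vup
        dCarel = (Itr - Irel) / (
            1.0 + CSQNmax * KmCSQN / ((Carel + KmCSQN) * (Carel + KmCSQN))
        )

        # Rush-Larsen gate updates
        S[i, 1] = _rl(m, am / (am + bm), 1.0 / (am + bm), dt)
        S[i, 2] = _rl(h, ah / (ah + bh), 1.0 / (ah + bh), dt)
        S[i, 3] = _rl(j, aj / (aj + bj), 1.0 / (aj + bj), dt)
        S[i, 4] = _rl(oa, oa_inf, tau_oa, dt)
        S[i, 5] = _rl(oi, oi_inf, tau_oi, dt)
        S[i, 6] = _rl(ua, ua_inf, tau_ua, dt)
        S[i, 7] = _rl(ui, ui_inf, tau_ui, dt)
        S[i, 8] = _rl(xr, xr_inf, tau_xr, dt)
        S[i, 9] = _rl(xs, xs_inf, tau_xs, dt)
        S[i, 10] = _rl(d, d_inf, tau_d, dt)
        S[i, 11] = _rl(f, f_inf, tau_f, dt)
        S[i, 12] = _rl(fca, fca_inf, tau_fca, dt)
        S[i, 13] = _rl(u, u_inf, tau_u, dt)
        S[i, 14] = _rl(vg, v_inf, tau_v, dt)
        S[i, 15] = _rl(w, w_inf, tau_w, dt)

        S[i, 0] = V + dt * (-Iion + istim[i])
        S[i, 16] = Nai + dt * dNai
        S[i, 17] = Ki + dt * dKi
        S[i, 18] = Cai + dt * (B1 / B2)
        S[i, 19] = Caup + dt * dCaup
        S[i, 20] = Carel + dt * dCarel


@njit(cache=True, inline="always")
def _rl(g, g_inf, tau, dt):
    return g_inf + (g - g_inf) * math.exp(-dt / tau)


# ---------------------------------------------------------------------------
# fast phenomenological 3-variable model (fast-inward / slow-outward /
# slow-inward current structure); voltage mapped to mV via V = -85 + 100 u.


@njit(cache=True)
def _fk_step(S, istim, dt, sc):
    # parameter set chosen for stable spiral re-entry on 2D sheets
    tau_vp = 3.33
    tau_v1m = 15.6
    tau_v2m = 5.0
    tau_wp = 350.0
    tau_wm = 80.0
    kk = 15.0
    u_csi = 0.45
    u_c = 0.15
    u_v = 0.04
    V0 = -85.0
    Vspan = 100.0

    n = S.shape[0]
    for i in range(n):
        # Only g_K1 has a workable counterpart among the three lumped
        # currents (the plateau repolarizing current), with square-root
        # attenuation because the lumped current responds far more steeply
        # to its time constant than a real membrane does to a conductance.
        # Scaling the fast inward current pushes this parameter set past
        # its propagation limit, so g_Na & friends are rendered as identity.
        tau_d = 0.407
        tau_0 = 9.0
        tau_r = 34.0 / math.sqrt(sc[i, 1])
        tau_si = 26.5
        u = (S[i, 0] - V0) / Vspan
        v = S[i, 1]
        w = S[i, 2]
        p = 1.0 if u >= u_c else 0.0
        q = 1.0 if u >= u_v else 0.0
        tau_vm = q * tau_v1m + (1.0 - q) * tau_v2m

        Jfi = -v * p * (1.0 - u) * (u - u_c) / tau_d
        Jso = u * (1.0 - p) / tau_0 + p / tau_r
        Jsi = -w * (1.0 + math.tanh(kk * (u - u_csi))) / (2.0 * tau_si)

        du = -(Jfi + Jso + Jsi) + istim[i] / Vspan
        dv = (1.0 - p) * (1.0 - v) / tau_vm - p * v / tau_vp
        dw = (1.0 - p) * (1.0 - w) / tau_wm - p * w / tau_wp

        u_new = min(max(u + dt * du, -0.05), 1.05)  # keeps Vm in [-90, +20]
        S[i, 0] = V0 + Vspan * u_new
        S[i, 1] = min(max(v + dt * dv, 0.0), 1.0)
        S[i, 2] = min(max(w + dt * dw, 0.0), 1.0)


# ---------------------------------------------------------------------------
# jitted integration drivers (record full state every rec_stride steps)


@njit(cache=True)
def _run_crn(S, amp, dt, n_steps, sc, rec, k, rec_stride, step0):
    istim = np.full(S.shape[0], amp)
    for step in range(n_steps):
        _crn_step(S, istim, dt, sc)
        gs = step0 + step + 1
        if gs % rec_stride == 0:
            rec[k] = S[0]
            k += 1
    return k


@njit(cache=True)
def _run_fk(S, amp, dt, n_steps, sc, rec, k, rec_stride, step0):
    istim = np.full(S.shape[0], amp)
    for step in range(n_steps):
        _fk_step(S, istim, dt, sc)
        gs = step0 + step + 1
        if gs % rec_stride == 0:
            rec[k] = S[0]
            k += 1
    return k


def _integrate_cell(
    model: MembraneModel,
    state: np.ndarray,
    t_end: float,
    dt: float,
    stim_times,
    stim_duration: float,
    stim_amplitude: float,
    record_every: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segmented single-cell integration; returns (t, states, final_state)."""
    s = np.ascontiguousarray(state, dtype=np.float64).reshape(1, -1).copy()
    n_steps = int(round(t_end / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    runner = _run_crn if model.name == "courtemanche" else _run_fk
    sc = np.tile(model.scale_vector(), (1, 1))
    # segment boundaries at stimulus edges, in units of steps
    edges = {0, n_steps}
    stim_times = sorted(float(t) for t in stim_times)
    for t0 in stim_times:
        edges.add(int(round(t0 / dt)))
        edges.add(int(round((t0 + stim_duration) / dt)))
    bounds = sorted(e for e in edges if 0 <= e <= n_steps)
    n_rec = n_steps // rec_stride + 1
    rec = np.empty((n_rec, s.shape[1]))
    rec[0] = s[0]
    k = 1
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        t_mid = (b0 + 0.5) * dt
        amp = 0.0
        for t0 in stim_times:
            if t0 <= t_mid < t0 + stim_duration:
                amp = stim_amplitude
                break
        k = runner(s, amp, dt, b1 - b0, sc, rec, k, rec_stride, b0)
    t_out = np.arange(k) * rec_stride * dt
    if not np.all(np.isfinite(s)):
        raise IntegrationError(f"non-finite state at t = {t_end} ms")
    return t_out, rec[:k], s[0]


# ---------------------------------------------------------------------------
# single-cell utilities


def step_cell(
    model: MembraneModel, state: np.ndarray, i_stim: float, dt: float
) -> np.ndarray:
    """One integration step of a single cell; returns the new state."""
    s = np.ascontiguousarray(state, dtype=np.float64).reshape(1, -1).copy()
    model.step(s, np.array([float(i_stim)]), dt)
    if not np.all(np.isfinite(s)):
        raise IntegrationError("non-finite state after single step")
    return s[0]


def simulate_cell(
    model: MembraneModel,
    t_end: float,
    dt: float = 0.02,
    stim_times: np.ndarray | list[float] = (),
    stim_duration: float = 2.0,
    stim_amplitude: float = 30.0,
    state: np.ndarray | None = None,
    record_every: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a single cell with square stimulus pulses.

    Returns ``(t, vm, final_state)`` with ``t``/``vm`` sampled every
    ``record_every`` ms.  Stimulus amplitude is in pA/pF.
    """
    s0 = model.rest_state() if state is None else np.asarray(state, float)
    t, states, final = _integrate_cell(
        model, s0, t_end, dt, stim_times, stim_duration, stim_amplitude, record_every
    )
    return t, states[:, 0], final


def apd94(trace: np.ndarray, dt: float) -> float:
    """Action potential duration at 94% repolarization, ms.

    Measured from the time of maximum upstroke velocity to the crossing of
    the level 94% of the way from the peak back to the pre-stimulus
    diastolic potential, with linear interpolation between samples.
    """
    vm = np.asarray(trace, dtype=float)
    if vm.size < 3:
        raise ValueError("trace too short")
    dv = np.diff(vm)
    i_up = int(np.argmax(dv))
    if dv[i_up] <= 0.5 * dt:  # < 0.5 mV/ms: no depolarization upstroke
        raise ValueError("no depolarization found in trace")
    v_dia = float(np.min(vm[: i_up + 1])) if i_up > 0 else float(vm[0])
    after = vm[i_up:]
    v_peak = float(np.max(after))
    level = v_peak - 0.94 * (v_peak - v_dia)
    i_peak = int(np.argmax(after))
    below = np.nonzero(after[i_peak:] <= level)[0]
    if below.size == 0:
        raise ValueError("trace does not repolarize to 94% within window")
    k = i_peak + below[0]
    if k == 0:
        return 0.0
    v1, v2 = after[k - 1], after[k]
    frac = (v1 - level) / (v1 - v2) if v2 != v1 else 0.0
    return float((k - 1 + frac) * dt)


def cell_erp_scan(
    model: MembraneModel,
    cl: float = 1000.0,
    resolution: float = 1.0,
    n_prepace: int = 8,
    dt: float = 0.02,
    s2_amplitude: float = 30.0,
    scan_start: float | None = None,
) -> float:
    """Exhaustive S1-S2 scan for the cell-level effective refractory period.

    After ``n_prepace`` steady S1 beats at cycle length ``cl``, S2 stimuli
    are delivered at increasing coupling intervals in steps of
    ``resolution``; returns the smallest coupling that produces an action
    potential (peak Vm >= 0 mV).  Serves as the oracle for the tissue-level
    binary search.
    """
    if resolution < 0.5:
        raise ValueError(f"resolution must be >= 0.5 ms, got {resolution}")
    stim_times = [i * cl for i in range(n_prepace)]
    # state at the last S1 onset
    _, _, s_pre = simulate_cell(
        model, stim_times[-1], dt, stim_times[:-1], record_every=cl
    )
    start = resolution if scan_start is None else scan_start
    couplings = np.arange(start, cl + resolution / 2, resolution)
    for ci in couplings:
        _, vm, _ = simulate_cell(
            model,
            ci + 80.0,
            dt,
            [0.0, ci],
            stim_amplitude=s2_amplitude,
            state=s_pre,
            record_every=0.5,
        )
        # capture = new action potential: peak Vm >= 0 mV plus a
        # regenerative upstroke clearly faster than the stimulus-driven
        # slope alone (graded sub-threshold responses fail the dV/dt test)
        i_s2 = int(round(ci * 2))
        seg = vm[i_s2 : i_s2 + 160]
        dvdt_max = float(np.max(np.diff(seg))) / 0.5
        if np.max(seg[5:]) >= 0.0 and dvdt_max >= 1.5 * s2_amplitude:
            return float(ci)
    raise RuntimeError(f"no capture at any coupling up to {cl} ms")


def limit_cycle_template(
    model: MembraneModel,
    cl: float,
    n_prepace: int = 20,
    dt: float = 0.02,
    sample_every: float = 1.0,
) -> np.ndarray:
    """Steady-pacing limit cycle sampled over one cycle length.

    Returns an array ``(n_frames, n_states)`` covering one period ``cl``
    starting at the maximum-upstroke-velocity sample, after ``n_prepace``
    conditioning beats.  Beat-to-beat APD94 alternans > 5 ms triggers a
    warning; the last beat is used regardless.
    """
    stim_times = [i * cl for i in range(n_prepace + 1)]
    t_end = (n_prepace + 1) * cl
    t_arr, traj, _ = _integrate_cell(
        model, model.rest_state(), t_end, dt, stim_times, 2.0, 30.0, sample_every
    )
    # alternans check on the last two beats
    last2 = traj[t_arr >= (n_prepace - 1) * cl, 0]
    n_per = int(round(cl / sample_every))
    if last2.size >= 2 * n_per:
        try:
            a1 = apd94(last2[:n_per], sample_every)
            a2 = apd94(last2[n_per : 2 * n_per], sample_every)
            if abs(a1 - a2) > 5.0:
                warnings.warn(
                    f"alternans detected: beat-to-beat APD94 difference "
                    f"{abs(a1 - a2):.1f} ms; using last beat",
                    stacklevel=2,
                )
        except ValueError:
            pass
    # last full cycle, rotated to start at max dVm/dt
    sel = (t_arr > n_prepace * cl) & (t_arr <= (n_prepace + 1) * cl)
    cycle = traj[sel]
    vm = cycle[:, 0]
    dv = np.diff(np.r_[vm, vm[0]])
    start = int(np.argmax(dv))
    return np.roll(cycle, -start, axis=0)
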