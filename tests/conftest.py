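"""Shared fixtures.

The expensive end-to-end artifacts (a PSD-seeded spiral movie, a
pacing-induced macro-reentry episode) are session-scoped and reused by
several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from reentrylab import fixtures, geometry, ionic, monodomain, protocols, psd


@pytest.fixture(scope="session")
def fk_model():
    return ionic.fast_test_model()


@pytest.fixture(scope="session")
def crn_model():
    return ionic.courtemanche_model()


@pytest.fixture(scope="session")
def fk_cell_props(fk_model):
    """Single-cell APD94 / ERP / strand CV of the fast model at sigma 0.2."""
    _, vm, _ = ionic.simulate_cell(fk_model, 900.0, 0.05, [10.0])
    apd = ionic.apd94(vm, 1.0)
    erp = ionic.cell_erp_scan(fk_model, cl=600.0, resolution=2.0, scan_start=150.0)
    geom = geometry.make_strand(201, 0.5, sigma=0.2)
    res = monodomain.run(
        geom, fk_model, [monodomain.StimulusSpec((0.0, 0.0), onset=1.0)],
        t_end=400.0, dt=0.05,
    )
    cv = monodomain.measure_cv(res, window=(30.0, 70.0))
    return {"apd94": apd, "erp": erp, "cv": cv}


@pytest.fixture(scope="session")
def spiral_run(fk_model):
    """PSD-seeded spiral on a homogeneous sheet, 1.6 s continuation.

    Cycle length follows the 5%-above-ERP rule for this membrane; the
    eikonal speed is the measured strand CV at the same conductivity.
    """
    sigma = 0.1
    strand = geometry.make_strand(201, 0.5, sigma=sigma)
    sres = monodomain.run(
        strand, fk_model, [monodomain.StimulusSpec((0.0, 0.0), onset=1.0)],
        t_end=500.0, dt=0.05,
    )
    speed = monodomain.measure_cv(sres, window=(30.0, 70.0))
    erp = ionic.cell_erp_scan(fk_model, cl=600.0, resolution=2.0, scan_start=150.0)
    cl = psd.psd_cycle_length(erp)
    geom = geometry.make_sheet(141, 141, 0.5, sigma=sigma)
    params = psd.PSDParams(ps_location=(35.0, 35.0), cl=cl, speed=speed)
    tmap = psd.spiral_activation_map(geom, params)
    template = ionic.limit_cycle_template(fk_model, cl, n_prepace=8, dt=0.05)
    state = psd.map_to_state(geom, fk_model, tmap, template, cl)
    res = monodomain.run(geom, fk_model, [], t_end=1600.0, dt=0.05, initial_state=state)
    return {
        "geom": geom, "params": params, "tmap": tmap, "result": res,
        "cl": cl, "speed": speed,
    }


@pytest.fixture(scope="session")
def flutter_episode():
    """PEERP-induced macro-reentry on the linear-barrier substrate."""
    geom, model, scales, site = fixtures.flutter_loop_substrate()
    backend = protocols.MonodomainBackend(
        geom, model, site, dt=0.1, node_scales=scales
    )
    res = protocols.run_peerp(
        backend, protocols.PEERPParams(max_beats=4, erp_first_guess=172.0)
    )
    return {"geom": geom, "model": model, "result": res, "site": site}


# -- scripted protocol backends ---------------------------------------------


class ScriptedBackend:
    """Deterministic stub: propagation above a fixed ERP, induction after a
    scripted number of delivered beats."""

    def __init__(self, erp: float = 150.0, induce_after: int | None = None):
        self.erp = erp
        self.induce_after = induce_after
        self.beats = 0
        self._sim = 0.0

    def deliver_beat(self, ci: float) -> bool:
        self.beats += 1
        self._sim += max(ci, 0.0)
        return self.beats == 1 or ci >= self.erp

    def trial_beat(self, ci: float) -> bool:
        self._sim += max(ci, 0.0)
        return ci >= self.erp

    def check_induction(self) -> bool:
        self._sim += 1500.0
        return self.induce_after is not None and self.beats >= self.induce_after

    @property
    def simulated_ms(self) -> float:
        return self._sim


@pytest.fixture
def scripted_backend_factory():
    return ScriptedBackend
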