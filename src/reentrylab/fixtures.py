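"""Canonical synthetic substrates for protocol studies and tests.

These builders define the desk-scale study conditions: membrane variants of
the fast phenomenological model with distinct refractoriness, a linear
nonconductive line of block with a slow-recovery region (supports
pacing-induced macro-reentry), fibrotic two-region sheets in the two
severity presets, and the spiral-seeding configuration.  All are plain
functions of a seed so tests, examples and the CLI share one source of
truth.
"""

from __future__ import annotations

import numpy as np

from . import geometry as G
from . import ionic, monodomain

__all__ = [
    "short_apd_fast_model",
    "flutter_loop_substrate",
    "gradient_sheet_substrate",
    "fibrotic_two_region_sheet",
    "erp_strand",
]


def short_apd_fast_model() -> ionic.MembraneModel:
    """Fast-model variant with moderately shortened refractoriness.

    A mildly raised repolarizing-current scale (g_K1 x 1.3) shortens the
    action potential enough that re-entrant wavelengths fit a 6 cm sheet
    while a 2 x 2 mm stimulus still ignites in 2D.
    """
    return ionic.MembraneModel("fast_test", {"g_K1": 1.3})


def flutter_loop_substrate(
    n: int = 121, h: float = 0.5, sigma: float = 0.15
) -> tuple[G.TissueGeometry, ionic.MembraneModel, np.ndarray, tuple[int, int]]:
    """Sheet with a linear nonconductive barrier and a slow-recovery patch.

    The barrier spans the sheet center with free ends; the region below it
    and to the right of the pacing site recovers more slowly, so a
    premature beat blocks there, travels around the barrier and re-enters:
    an anatomical macro-reentry (flutter) circuit.  Returns
    ``(geom, model, node_scales, site)``; the site sits below the barrier
    center.
    """
    model = short_apd_fast_model()
    geom = G.make_sheet(n, n, h, sigma=sigma)
    mid = (n - 1) // 2
    x0, x1 = n // 6, n - n // 6
    geom.labels[mid - 2 : mid, x0:x1] = G.NONCONDUCTIVE
    geom.sigma[mid - 2 : mid, x0:x1] = G.NONCONDUCTIVE_SIGMA
    scales = monodomain.node_scale_map(geom, model).reshape(n, n, 7)
    scales[: mid - 1, mid + 10 :, 1] = 1.0  # slower recovery below-right
    # site below the barrier, left of the slow-recovery patch: premature
    # beats block rightward into the patch and circulate around the barrier
    site = (mid - 10, mid - 10)
    return geom, model, scales.reshape(-1, 7), site


def gradient_sheet_substrate(
    n: int = 121, h: float = 0.5, sigma: float = 0.2
) -> tuple[G.TissueGeometry, ionic.MembraneModel, np.ndarray, tuple[int, int]]:
    """Sheet with a step in repolarization rate between left/right halves.

    Premature stimulation near the interface can block into the
    longer-refractory half; used for vulnerable-window experiments.
    """
    model = short_apd_fast_model()
    geom = G.make_sheet(n, n, h, sigma=sigma)
    scales = monodomain.node_scale_map(geom, model).reshape(n, n, 7)
    scales[:, n // 2 :, 1] = 1.0
    site = (n // 8, n // 2 - 10)
    return geom, model, scales.reshape(-1, 7), site


def fibrotic_two_region_sheet(
    preset: str = "UIV",
    n: int = 121,
    h: float = 0.5,
    sigma: float = 0.15,
    seed: int = 0,
) -> G.TissueGeometry:
    """Two-region ("LAW"/"RAW") sheet with a fibrosis severity preset.

    ``preset`` is ``"UII"`` (19% LAW / 5% RAW fibrotic) or ``"UIV"``
    (39% / 11%); half of the fibrotic elements are percolation barriers,
    half conduct with cytokine-remodeled membranes.
    """
    geom = G.make_two_region_sheet(n, n, h, sigma=sigma)
    maker = {"UII": G.utah_ii_preset, "UIV": G.utah_iv_preset}[preset]
    return G.apply_fibrosis(geom, maker(seed=seed))


def erp_strand(
    length_mm: float = 40.0,
    h: float = 0.5,
    sigma: float = 0.2,
    model: ionic.MembraneModel | None = None,
) -> tuple[G.TissueGeometry, ionic.MembraneModel, tuple[int, int]]:
    """Short strand with a mid-strand pacing site for ERP experiments."""
    geom = G.make_strand(int(round(length_mm / h)) + 1, h, sigma=sigma)
    model = model or short_apd_fast_model()
    site = (0, geom.nx // 2)
    return geom, model, site
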