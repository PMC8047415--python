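"""Synthetic tissue domains: strands, sheets, two-region surrogates.

Geometries are regular node-centered grids with spacing ``h`` (mm), origin at
the domain corner.  Nodes carry the transmembrane voltage during simulation;
the (ny-1) x (nx-1) cells between them ("elements") carry region labels and
conductivities.  Fibrosis is modeled by relabeling elements inside named
regions: half of the fibrotic elements become electrically decoupled passive
barriers (sigma = 1e-7 S/m, "percolation"), the other half keep conducting but
are flagged for cytokine-remodeled membrane kinetics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

# element labels
WORKING = 0
FIBROTIC_REMODELED = 1
NONCONDUCTIVE = 2

#: conductivity assigned to electrically decoupled (percolation) elements, S/m
NONCONDUCTIVE_SIGMA = 1e-7

#: default bulk conductivity of working myocardium, S/m (tunable, see monodomain)
DEFAULT_SIGMA = 0.30


@dataclass
class TissueGeometry:
    """Discretized rectangular tissue domain.

    Attributes
    ----------
    kind : str
        ``"strand"`` (1D, ny == 1) or ``"sheet"`` (2D).
    h : float
        Node spacing in mm.
    shape : tuple
        Node counts ``(ny, nx)``.
    labels : ndarray
        Per-element region label, shape ``(max(ny-1,1), nx-1)``.
    sigma : ndarray
        Per-element conductivity in S/m, same shape as ``labels``.
    named_regions : dict
        name -> boolean element mask (e.g. ``"LAW"``, ``"RAW"``).
    segments : ndarray
        Per-element segment id; segments partition the domain.
    """

    kind: str
    h: float
    shape: tuple[int, int]
    labels: np.ndarray
    sigma: np.ndarray
    named_regions: dict[str, np.ndarray] = field(default_factory=dict)
    segments: np.ndarray | None = None
    fiber_angle: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"node spacing h must be positive, got {self.h}")
        if np.any(self.sigma < 0):
            raise ValueError("conductivities must be non-negative")
        if self.segments is None:
            self.segments = np.zeros_like(self.labels, dtype=np.int32)

    # -- derived quantities -------------------------------------------------

    @property
    def ny(self) -> int:
        return self.shape[0]

    @property
    def nx(self) -> int:
        return self.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.ny * self.nx

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical size (Lx, Ly) spanned by the node grid, mm."""
        return ((self.nx - 1) * self.h, (self.ny - 1) * self.h)

    def node_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate arrays (x, y) in mm, each of shape (ny, nx)."""
        y, x = np.mgrid[0 : self.ny, 0 : self.nx] * self.h
        return x, y

    def conductive_elements(self) -> np.ndarray:
        return self.sigma > 10 * NONCONDUCTIVE_SIGMA

    def conductive_nodes(self) -> np.ndarray:
        """Boolean (ny, nx) mask: node touches >= 1 conductive element."""
        cond = self.conductive_elements()
        mask = np.zeros((self.ny, self.nx), dtype=bool)
        if self.ny == 1:
            mask[0, :-1] |= cond[0]
            mask[0, 1:] |= cond[0]
            return mask
        mask[:-1, :-1] |= cond
        mask[:-1, 1:] |= cond
        mask[1:, :-1] |= cond
        mask[1:, 1:] |= cond
        return mask

    def nearest_node(self, pos: tuple[float, float]) -> tuple[int, int]:
        """(row, col) of the node nearest to position (x, y) in mm."""
        x, y = pos
        j = int(round(x / self.h))
        i = int(round(y / self.h))
        return (min(max(i, 0), self.ny - 1), min(max(j, 0), self.nx - 1))

    def node_pos(self, idx: tuple[int, int]) -> tuple[float, float]:
        i, j = idx
        return (j * self.h, i * self.h)

    def copy(self) -> "TissueGeometry":
        return dataclasses.replace(
            self,
            labels=self.labels.copy(),
            sigma=self.sigma.copy(),
            named_regions={k: v.copy() for k, v in self.named_regions.items()},
            segments=None if self.segments is None else self.segments.copy(),
        )


@dataclass
class FibrosisPreset:
    """Fibrosis burden per named region, exact-count percolation sampling.

    ``fractions`` maps region name -> fibrotic fraction in [0, 1];
    ``nonconductive_fraction`` of the selected fibrotic elements become
    passive barriers, the rest are cytokine-remodeled but conducting.
    """

    name: str
    fractions: dict[str, float]
    nonconductive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for region, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for region {region!r} outside [0,1]: {f}")
        if not 0.0 <= self.nonconductive_fraction <= 1.0:
            raise ValueError("nonconductive_fraction outside [0,1]")


def utah_ii_preset(seed: int = 0) -> FibrosisPreset:
    """Utah stage II surrogate: 19% of LAW, 5% of RAW fibrotic."""
    return FibrosisPreset("UII", {"LAW": 0.19, "RAW": 0.05}, seed=seed)


def utah_iv_preset(seed: int = 0) -> FibrosisPreset:
    """Utah stage IV surrogate: 39% of LAW, 11% of RAW fibrotic."""
    return FibrosisPreset("UIV", {"LAW": 0.39, "RAW": 0.11}, seed=seed)


@dataclass
class PacingSiteSet:
    """Regular grid of stimulation sites snapped to conductive nodes."""

    d_mm: float
    sites: list[tuple[int, int]]          # node indices (row, col)
    margin_mm: float = 0.0
    dropped: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, geom: TissueGeometry) -> list[tuple[float, float]]:
        return [geom.node_pos(s) for s in self.sites]


# ---------------------------------------------------------------------------
# constructors


def make_strand(nx: int, h: float, sigma: float = DEFAULT_SIGMA) -> TissueGeometry:
    """Homogeneous 1D strand of ``nx`` nodes at spacing ``h`` mm."""
    if nx < 3:
        raise ValueError(f"strand needs >= 3 nodes, got {nx}")
    if h <= 0:
        raise ValueError(f"node spacing must be positive, got {h}")
    n_el = nx - 1
    labels = np.zeros((1, n_el), dtype=np.int8)
    sig = np.full((1, n_el), sigma, dtype=np.float64)
    return TissueGeometry("strand", h, (1, nx), labels, sig)


def make_sheet(nx: int, ny: int, h: float, sigma: float = DEFAULT_SIGMA) -> TissueGeometry:
    """Homogeneous working-myocardium sheet of ``ny x nx`` nodes."""
    if nx < 3 or ny < 3:
        raise ValueError(f"sheet needs >= 3 nodes per axis, got ({nx}, {ny})")
    if h <= 0:
        raise ValueError(f"node spacing must be positive, got {h}")
    labels = np.zeros((ny - 1, nx - 1), dtype=np.int8)
    sig = np.full((ny - 1, nx - 1), sigma, dtype=np.float64)
    return TissueGeometry("sheet", h, (ny, nx), labels, sig)


def make_two_region_sheet(
    nx: int, ny: int, h: float, sigma: float = DEFAULT_SIGMA
) -> TissueGeometry:
    """Sheet split into left/right named halves ("LAW" / "RAW" surrogates)."""
    geom = make_sheet(nx, ny, h, sigma)
    n_el_x = nx - 1
    cols = np.arange(n_el_x)
    left = np.zeros_like(geom.labels, dtype=bool)
    left[:, cols < n_el_x // 2] = True
    geom.named_regions["LAW"] = left
    geom.named_regions["RAW"] = ~left
    return geom


# ---------------------------------------------------------------------------
# fibrosis


def apply_fibrosis(geom: TissueGeometry, preset: FibrosisPreset) -> TissueGeometry:
    """Relabel exact counts of elements in each named region as fibrotic.

    Within each region exactly ``round(fraction * |region|)`` elements are
    drawn without replacement; of those exactly
    ``round(nonconductive_fraction * count)`` become passive barriers with
    sigma = 1e-7 S/m, the remainder fibrotic-remodeled.  Deterministic for a
    given seed.
    """
    out = geom.copy()
    rng = np.random.default_rng(preset.seed)
    for region in sorted(preset.fractions):
        if region not in out.named_regions:
            raise KeyError(f"unknown named region {region!r}")
        mask = out.named_regions[region]
        idx = np.flatnonzero(mask.ravel())
        n_fib = int(round(preset.fractions[region] * idx.size))
        chosen = rng.choice(idx, size=n_fib, replace=False)
        n_nc = int(round(preset.nonconductive_fraction * n_fib))
        nc = chosen[:n_nc]
        rem = chosen[n_nc:]
        flat_labels = out.labels.ravel()
        flat_sigma = out.sigma.ravel()
        flat_labels[nc] = NONCONDUCTIVE
        flat_sigma[nc] = NONCONDUCTIVE_SIGMA
        flat_labels[rem] = FIBROTIC_REMODELED
    return out


# ---------------------------------------------------------------------------
# segments


def partition_segments(geom: TissueGeometry, k: int) -> TissueGeometry:
    """Partition the element grid into a k x k block grid of segments."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out = geom.copy()
    ney, nex = out.labels.shape
    rows = np.minimum((np.arange(ney) * k) // ney, k - 1)
    cols = np.minimum((np.arange(nex) * k) // nex, k - 1)
    out.segments = (rows[:, None] * k + cols[None, :]).astype(np.int32)
    return out


# ---------------------------------------------------------------------------
# pacing sites


def make_pacing_sites(
    geom: TissueGeometry, d_mm: float = 10.0, margin_mm: float = 5.0
) -> PacingSiteSet:
    """Regular site grid at spacing ``d_mm``, snapped to conductive nodes.

    Candidate positions run from ``margin_mm`` to ``extent - margin_mm`` on
    each axis in steps of ``d_mm``.  A candidate landing on nonconductive
    tissue moves to the nearest conductive node within ``d_mm / 2``; failing
    that it is dropped (and recorded).
    """
    if d_mm < 2 * geom.h:
        raise ValueError(
            f"site spacing {d_mm} mm must be >= twice the grid spacing {geom.h} mm"
        )
    lx, ly = geom.extent_mm
    xs = _axis_candidates(lx, d_mm, margin_mm)
    ys = _axis_candidates(ly, d_mm, margin_mm) if geom.ny > 1 else np.array([0.0])
    cond = geom.conductive_nodes()
    ci, cj = np.nonzero(cond)
    sites: list[tuple[int, int]] = []
    dropped: list[tuple[float, float]] = []
    for y in ys:
        for x in xs:
            i, j = geom.nearest_node((x, y))
            if cond[i, j]:
                sites.append((i, j))
                continue
            dist2 = (ci - i) ** 2 + (cj - j) ** 2
            best = int(np.argmin(dist2))
            if np.sqrt(dist2[best]) * geom.h <= d_mm / 2:
                sites.append((int(ci[best]), int(cj[best])))
            else:
                dropped.append((x, y))
    # de-duplicate while preserving order (snapping can merge candidates)
    seen: set[tuple[int, int]] = set()
    unique = [s for s in sites if not (s in seen or seen.add(s))]
    return PacingSiteSet(d_mm=d_mm, sites=unique, margin_mm=margin_mm, dropped=dropped)


def _axis_candidates(extent: float, d: float, margin: float) -> np.ndarray:
    hi = extent - margin
    if hi < margin:
        return np.array([extent / 2.0])
    n = int(np.floor((hi - margin) / d + 1e-9)) + 1
    return margin + d * np.arange(n)


# ---------------------------------------------------------------------------
# geodesic distance


def _conductive_graph(geom: TissueGeometry) -> tuple[csr_matrix, np.ndarray]:
    """8-neighbor graph over conductive nodes, Euclidean edge weights in mm."""
    cond = geom.conductive_nodes()
    ny, nx = cond.shape
    idx = -np.ones((ny, nx), dtype=np.int64)
    nodes = np.flatnonzero(cond.ravel())
    idx.ravel()[nodes] = np.arange(nodes.size)
    rows, cols, w = [], [], []
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    for di, dj, wt in offsets:
        src_i, src_j = np.nonzero(cond)
        ti, tj = src_i + di, src_j + dj
        ok = (ti >= 0) & (ti < ny) & (tj >= 0) & (tj < nx)
        si, sj, ti, tj = src_i[ok], src_j[ok], ti[ok], tj[ok]
        ok2 = cond[ti, tj]
        si, sj, ti, tj = si[ok2], sj[ok2], ti[ok2], tj[ok2]
        rows.append(idx[si, sj])
        cols.append(idx[ti, tj])
        w.append(np.full(si.size, wt * geom.h))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    ww = np.concatenate(w)
    n = nodes.size
    g = csr_matrix((np.r_[ww, ww], (np.r_[r, c], np.r_[c, r])), shape=(n, n))
    return g, idx


def geodesic_distance(
    geom: TissueGeometry, a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Shortest-path distance (mm) between positions through conductive tissue.

    Raises ``ValueError`` if either endpoint is off conductive tissue or the
    endpoints are disconnected.
    """
    g, idx = _conductive_graph(geom)
    ia = idx[geom.nearest_node(a)]
    ib = idx[geom.nearest_node(b)]
    if ia < 0 or ib < 0:
        raise ValueError("endpoint not on conductive tissue")
    if ia == ib:
        return 0.0
    d = dijkstra(g, directed=False, indices=ia)[ib]
    if not np.isfinite(d):
        raise ValueError("endpoints are disconnected through conductive tissue")
    return float(d)
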