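"""Per-site vulnerability maps and the sensitivity analyses.

Each pacing site is probed independently from the same rested tissue
state; the outcome (induced / episode class / beats used) is aggregated
per spatial segment.  Two sensitivity procedures are provided: recovery of
stable-llPS-maintaining segments when the pacing grid is thinned
(inter-point spacing sensitivity), and stability of the inducing-point
count when the ERP search resolution of PEERP is coarsened.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import geometry as G
from . import ionic, phase, protocols

__all__ = [
    "SiteOutcome",
    "VulnerabilityReport",
    "run_vulnerability_map",
    "spacing_sensitivity",
    "thin_sites",
    "erp_tolerance_sweep",
    "maintenance_summary",
]


@dataclass
class SiteOutcome:
    site: tuple[int, int]
    position_mm: tuple[float, float]
    segment: int
    induced: bool
    episode: str
    beats_delivered: int
    inducing_ci: float | None
    simulated_ms: float
    stable_center_mm: tuple[float, float] | None = None
    maintain_segment: int | None = None
    distance_mm: float | None = None
    status: str = "ok"


@dataclass
class VulnerabilityReport:
    protocol: str
    outcomes: list[SiteOutcome] = field(default_factory=list)

    @property
    def n_inducing(self) -> int:
        return sum(o.induced for o in self.outcomes)

    def class_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for o in self.outcomes:
            totals[o.episode] = totals.get(o.episode, 0) + 1
        return totals

    def inducing_segments(self) -> set[int]:
        return {o.segment for o in self.outcomes if o.induced}

    def stable_segments(self) -> set[int]:
        """Segments maintaining a stable llPS (segment of the path center,
        falling back to the inducing site's segment)."""
        out = set()
        for o in self.outcomes:
            if o.episode == "stable_llPS":
                out.add(o.maintain_segment if o.maintain_segment is not None else o.segment)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(o) for o in self.outcomes])

    def to_json(self, **meta) -> str:
        return json.dumps(
            {
                "protocol": self.protocol,
                **meta,
                "n_sites": len(self.outcomes),
                "n_inducing": self.n_inducing,
                "class_totals": self.class_totals(),
                "outcomes": [asdict(o) for o in self.outcomes],
            },
            indent=2,
            default=lambda x: x.item() if hasattr(x, "item") else list(x),
        )


def _segment_of(geom: G.TissueGeometry, site: tuple[int, int]) -> int:
    i, j = site
    ey, ex = geom.segments.shape
    return int(geom.segments[min(i, ey - 1), min(j, ex - 1)])


def _analyze_continuation(cont, geom: G.TissueGeometry, induced: bool):
    """Episode class + trajectories from a continuation movie."""
    if cont is None or not induced:
        return phase.EpisodeClass(label="none"), []
    ph, _valid = phase.compute_phase(cont.vm, cont.dt_out)
    lag = cont.vm.shape[0] - ph.shape[0]
    dets = [phase.detect_ps(ph[k], h=geom.h) for k in range(ph.shape[0])]
    trajs = phase.track_ps(dets, cont.times[lag:], v_max=1.0)
    ec = phase.classify_episode(cont.vm, cont.times, trajs, induced=induced, h=geom.h)
    return ec, trajs


def run_vulnerability_map(
    geom: G.TissueGeometry,
    model: ionic.MembraneModel,
    protocol_params,
    sites: G.PacingSiteSet,
    dt: float = 0.02,
    node_scales: np.ndarray | None = None,
    backend_factory=None,
) -> VulnerabilityReport:
    """Run one induction protocol from every pacing site.

    ``protocol_params`` is an :class:`reentrylab.protocols.RPParams` or
    :class:`reentrylab.protocols.PEERPParams`.  Sites run independently
    from identical rested initial states; per-site failures are recorded
    in the outcome's ``status`` rather than aborting the map.
    """
    if len(sites) == 0:
        raise ValueError("empty pacing-site set")
    is_peerp = isinstance(protocol_params, protocols.PEERPParams)
    report = VulnerabilityReport(protocol="PEERP" if is_peerp else "RP")
    for site in sites.sites:
        try:
            if backend_factory is not None:
                backend = backend_factory(site)
            else:
                backend = protocols.MonodomainBackend(
                    geom, model, site, dt=dt, node_scales=node_scales
                )
            if is_peerp:
                res = protocols.run_peerp(backend, protocol_params)
            else:
                res = protocols.run_rp(backend, protocol_params)
            ec, trajs = _analyze_continuation(res.continuation, geom, res.induced)
            outcome = SiteOutcome(
                site=site,
                position_mm=geom.node_pos(site),
                segment=_segment_of(geom, site),
                induced=res.induced,
                episode=ec.label,
                beats_delivered=res.beats_delivered,
                inducing_ci=res.inducing_ci,
                simulated_ms=res.simulated_ms,
                status=res.status,
            )
            if ec.label == "stable_llPS":
                now = float(res.continuation.times[-1])
                stable = [
                    tr
                    for tr in trajs
                    if tr.t and phase.classify_llps(tr, now) == "stable_llPS"
                ]
                if stable:
                    center = stable[0].path_center(now - 1500.0, now)
                    outcome.stable_center_mm = center
                    outcome.maintain_segment = _segment_of(
                        geom, geom.nearest_node(center)
                    )
                    try:
                        outcome.distance_mm = G.geodesic_distance(
                            geom, geom.node_pos(site), center
                        )
                    except ValueError:
                        outcome.distance_mm = None
            report.outcomes.append(outcome)
        except (protocols.monodomain.SolverError, RuntimeError, ValueError) as exc:
            report.outcomes.append(
                SiteOutcome(
                    site=site,
                    position_mm=geom.node_pos(site),
                    segment=_segment_of(geom, site),
                    induced=False,
                    episode="none",
                    beats_delivered=0,
                    inducing_ci=None,
                    simulated_ms=0.0,
                    status=f"failed: {exc}",
                )
            )
    return report


# ---------------------------------------------------------------------------
# sensitivity analyses


def thin_sites(
    sites: G.PacingSiteSet, geom: G.TissueGeometry, d_mm: float
) -> list[tuple[int, int]]:
    """Subset of ``sites`` approximating a grid of spacing ``d_mm``.

    Greedy selection in site order: a site joins the subset if it is at
    least ``d_mm - h`` from every already-selected site.
    """
    chosen: list[tuple[int, int]] = []
    for s in sites.sites:
        x, y = geom.node_pos(s)
        ok = all(
            np.hypot(x - geom.node_pos(c)[0], y - geom.node_pos(c)[1])
            >= d_mm - geom.h
            for c in chosen
        )
        if ok:
            chosen.append(s)
    return chosen


def spacing_sensitivity(
    report: VulnerabilityReport,
    subsets: dict[float, list[tuple[int, int]]],
) -> dict[float, float]:
    """Stable-llPS recovery percentage per thinned pacing grid.

    For each spacing ``d`` the percentage of the full map's
    stable-llPS-maintaining segments that are still found when only the
    subset's sites are paced.
    """
    def seg_of(o: SiteOutcome) -> int:
        return o.maintain_segment if o.maintain_segment is not None else o.segment

    base_segments = {
        seg_of(o) for o in report.outcomes if o.episode == "stable_llPS"
    }
    by_site = {o.site: o for o in report.outcomes}
    result: dict[float, float] = {}
    for d, subset in subsets.items():
        if not subset:
            raise ValueError(f"empty subset for spacing {d}")
        found = {
            seg_of(by_site[s])
            for s in subset
            if s in by_site and by_site[s].episode == "stable_llPS"
        }
        if not base_segments:
            result[d] = 100.0 if not found else 0.0
        else:
            result[d] = 100.0 * len(found & base_segments) / len(base_segments)
    return result


def erp_tolerance_sweep(
    geom: G.TissueGeometry,
    model: ionic.MembraneModel,
    sites: G.PacingSiteSet,
    tolerances: list[float],
    peerp_params: protocols.PEERPParams,
    dt: float = 0.02,
    node_scales: np.ndarray | None = None,
) -> dict[float, int]:
    """Inducing-point count per ERP-search resolution.

    Re-runs the PEERP map with the ERP binary search stopped at each
    temporal tolerance; the stability of the counts as the tolerance grows
    is the readout.
    """
    counts: dict[float, int] = {}
    for tol in tolerances:
        params = protocols.PEERPParams(
            max_beats=peerp_params.max_beats,
            erp_resolution=tol,
            ring_mm=peerp_params.ring_mm,
            threshold_mv=peerp_params.threshold_mv,
            erp_first_guess=peerp_params.erp_first_guess,
        )
        rep = run_vulnerability_map(
            geom, model, params, sites, dt=dt, node_scales=node_scales
        )
        counts[tol] = rep.n_inducing
    return counts


def maintenance_summary(reports: list[VulnerabilityReport]) -> pd.DataFrame:
    """Per-segment stable-llPS maintenance table across protocol reports.

    One row per (protocol, segment) with the number of inducing points
    whose stable llPS anchored there and the geodesic distances from the
    inducing sites to the llPS path centers.
    """
    rows = []
    for rep in reports:
        seg_hits: dict[int, list[float]] = {}
        for o in rep.outcomes:
            if o.episode != "stable_llPS":
                continue
            seg = o.segment
            seg_hits.setdefault(seg, [])
            if o.distance_mm is not None:
                seg_hits[seg].append(o.distance_mm)
        for seg, dists in sorted(seg_hits.items()):
            rows.append(
                {
                    "protocol": rep.protocol,
                    "segment": seg,
                    "n_stable": sum(
                        1
                        for o in rep.outcomes
                        if o.episode == "stable_llPS" and o.segment == seg
                    ),
                    "mean_distance_mm": float(np.mean(dists)) if dists else np.nan,
                    "distances_mm": dists,
                }
            )
    return pd.DataFrame(
        rows, columns=["protocol", "segment", "n_stable", "mean_distance_mm", "distances_mm"]
    )
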