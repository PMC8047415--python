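"""Vulnerability maps and sensitivity analyses."""

import numpy as np
import pytest

from reentrylab import fixtures, geometry as G, phase, protocols, vulnerability as V


def _outcome(site, seg, episode, maintain=None, dist=None):
    return V.SiteOutcome(
        site=site,
        position_mm=(float(site[1]), float(site[0])),
        segment=seg,
        induced=episode != "none",
        episode=episode,
        beats_delivered=3,
        inducing_ci=200.0 if episode != "none" else None,
        simulated_ms=5000.0,
        maintain_segment=maintain,
        distance_mm=dist,
    )


class TestRunVulnerabilityMap:
    def test_homogeneous_sheet_has_no_inducing_points(self, fk_model):
        geom = G.make_sheet(61, 61, 0.5, sigma=0.2)
        geom = G.partition_segments(geom, 2)
        sites = G.PacingSiteSet(d_mm=15.0, sites=[(30, 20), (30, 40)])
        params = protocols.PEERPParams(max_beats=2, erp_first_guess=230.0)
        report = V.run_vulnerability_map(
            geom, fk_model, params, sites, dt=0.1
        )
        assert report.n_inducing == 0
        assert all(o.episode == "none" for o in report.outcomes)
        assert all(o.status == "ok" for o in report.outcomes)

    def test_reentry_substrate_reports_inducing_site_and_segment(self):
        geom, model, scales, site = fixtures.flutter_loop_substrate()
        geom = G.partition_segments(geom, 2)
        sites = G.PacingSiteSet(d_mm=10.0, sites=[site])
        params = protocols.PEERPParams(max_beats=4, erp_first_guess=172.0)
        report = V.run_vulnerability_map(
            geom, model, params, sites, dt=0.1, node_scales=scales
        )
        assert report.n_inducing == 1
        o = report.outcomes[0]
        assert o.episode in ("Fl", "Multi", "nonstable_llPS", "stable_llPS")
        assert o.segment == int(
            geom.segments[min(site[0], geom.segments.shape[0] - 1),
                          min(site[1], geom.segments.shape[1] - 1)]
        )
        assert report.inducing_segments() == {o.segment}

    def test_permuting_site_order_gives_identical_outcomes(self, fk_model):
        geom = G.make_sheet(61, 61, 0.5, sigma=0.2)
        a = G.PacingSiteSet(d_mm=10.0, sites=[(30, 20), (30, 40)])
        b = G.PacingSiteSet(d_mm=10.0, sites=[(30, 40), (30, 20)])
        params = protocols.PEERPParams(max_beats=1, erp_first_guess=230.0)
        ra = V.run_vulnerability_map(geom, fk_model, params, a, dt=0.1)
        rb = V.run_vulnerability_map(geom, fk_model, params, b, dt=0.1)
        da = {o.site: (o.induced, o.episode, o.beats_delivered) for o in ra.outcomes}
        db = {o.site: (o.induced, o.episode, o.beats_delivered) for o in rb.outcomes}
        assert da == db

    def test_empty_site_set_rejected(self, fk_model):
        geom = G.make_sheet(21, 21, 0.5)
        with pytest.raises(ValueError, match="empty"):
            V.run_vulnerability_map(
                geom, fk_model,
                protocols.PEERPParams(max_beats=1, erp_first_guess=200.0),
                G.PacingSiteSet(d_mm=10.0, sites=[]),
            )


class TestSpacingSensitivity:
    def _report(self):
        rep = V.VulnerabilityReport(protocol="PEERP")
        # 8 stable-llPS sites anchoring in 8 distinct segments
        for k in range(8):
            rep.outcomes.append(_outcome((k, k), seg=k, episode="stable_llPS",
                                         maintain=k, dist=10.0 + k))
        rep.outcomes.append(_outcome((9, 9), seg=8, episode="none"))
        return rep

    def test_full_subset_recovers_everything(self):
        rep = self._report()
        subsets = {10.0: [o.site for o in rep.outcomes]}
        assert V.spacing_sensitivity(rep, subsets) == {10.0: 100.0}

    def test_partial_subset_percentage(self):
        rep = self._report()
        subsets = {15.0: [(k, k) for k in range(5)]}  # 5 of 8 segments
        assert V.spacing_sensitivity(rep, subsets)[15.0] == pytest.approx(62.5)

    def test_subset_without_stable_sites_recovers_nothing(self):
        rep = self._report()
        subsets = {30.0: [(9, 9)]}
        assert V.spacing_sensitivity(rep, subsets)[30.0] == 0.0

    def test_nested_subsets_are_monotone(self):
        rep = self._report()
        sub = [o.site for o in rep.outcomes]
        subsets = {10.0: sub, 15.0: sub[:6], 20.0: sub[:4], 30.0: sub[:2]}
        pct = V.spacing_sensitivity(rep, subsets)
        vals = [pct[d] for d in sorted(pct)]
        assert vals == sorted(vals, reverse=True)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty subset"):
            V.spacing_sensitivity(self._report(), {20.0: []})

    def test_thin_sites_respects_minimum_spacing(self):
        geom = G.make_sheet(101, 101, 0.5)
        sites = G.make_pacing_sites(geom, d_mm=10.0, margin_mm=5.0)
        subset = V.thin_sites(sites, geom, 20.0)
        assert 0 < len(subset) < len(sites)
        for i, a in enumerate(subset):
            for b in subset[i + 1 :]:
                pa, pb = geom.node_pos(a), geom.node_pos(b)
                assert np.hypot(pa[0] - pb[0], pa[1] - pb[1]) >= 20.0 - geom.h


class TestErpToleranceSweep:
    def test_counts_stable_across_tolerances_on_strand(self):
        geom, model, site = fixtures.erp_strand()
        sites = G.PacingSiteSet(d_mm=10.0, sites=[site])
        params = protocols.PEERPParams(max_beats=2, erp_first_guess=172.0)
        counts = V.erp_tolerance_sweep(
            geom, model, sites, [1.0, 8.0], params, dt=0.05
        )
        # homogeneous strand: not inducible at any ERP resolution
        assert counts[1.0] == counts[8.0] == 0


class TestMaintenanceSummary:
    def test_distances_and_counts_tabulated(self):
        rep = V.VulnerabilityReport(protocol="PEERP")
        rep.outcomes.append(_outcome((0, 0), seg=1, episode="stable_llPS",
                                     maintain=2, dist=40.0))
        rep.outcomes.append(_outcome((5, 5), seg=1, episode="stable_llPS",
                                     maintain=2, dist=42.0))
        rep.outcomes.append(_outcome((9, 9), seg=3, episode="Fl"))
        df = V.maintenance_summary([rep])
        assert len(df) == 1
        row = df.iloc[0]
        assert row["segment"] == 1
        assert row["n_stable"] == 2
        assert row["mean_distance_mm"] == pytest.approx(41.0)

    def test_no_stable_llps_gives_empty_table(self):
        rep = V.VulnerabilityReport(protocol="RP")
        rep.outcomes.append(_outcome((0, 0), seg=0, episode="Multi"))
        df = V.maintenance_summary([rep])
        assert df.empty

    def test_stationary_rotor_distance_near_zero(self, spiral_run):
        # a rotor anchored at the seeding site: geodesic distance from the
        # site to the llPS path center is small
        res = spiral_run["result"]
        geom = spiral_run["geom"]
        ph, _ = phase.compute_phase(res.vm, res.dt_out)
        lag = res.vm.shape[0] - ph.shape[0]
        dets = [phase.detect_ps(ph[k], h=geom.h) for k in range(ph.shape[0])]
        trajs = phase.track_ps(dets, res.times[lag:], v_max=1.0, gap_bridge=1)
        main = max(trajs, key=lambda tr: tr.lifetime)
        center = main.path_center(res.times[-1] - 1500.0, res.times[-1])
        d = G.geodesic_distance(geom, spiral_run["params"].ps_location, center)
        assert d < 25.0  # meander stays near the seeded core


class TestReportSerialization:
    def test_json_roundtrip_fields(self):
        rep = V.VulnerabilityReport(protocol="PEERP")
        rep.outcomes.append(_outcome((1, 2), seg=0, episode="stable_llPS",
                                     maintain=1, dist=12.0))
        import json

        payload = json.loads(rep.to_json(seed=7))
        assert payload["protocol"] == "PEERP"
        assert payload["seed"] == 7
        assert payload["n_inducing"] == 1
        assert payload["outcomes"][0]["distance_mm"] == 12.0

    def test_identical_runs_serialize_identically(self, fk_model):
        geom = G.make_sheet(61, 61, 0.5, sigma=0.2)
        sites = G.PacingSiteSet(d_mm=10.0, sites=[(30, 30)])
        params = protocols.PEERPParams(max_beats=1, erp_first_guess=230.0)
        a = V.run_vulnerability_map(geom, fk_model, params, sites, dt=0.1)
        b = V.run_vulnerability_map(geom, fk_model, params, sites, dt=0.1)
        assert a.to_json(seed=1) == b.to_json(seed=1)
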