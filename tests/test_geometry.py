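"""Synthetic domains: construction, fibrosis sampling, sites, segments,
geodesic distances."""

import networkx as nx
import numpy as np
import pytest

from reentrylab import geometry as G


class TestSheets:
    def test_smallest_valid_sheet(self):
        g = G.make_sheet(3, 3, 0.5)
        assert g.n_nodes == 9
        assert g.labels.size == 4
        assert np.all(g.labels == G.WORKING)

    def test_physical_extent(self):
        g = G.make_sheet(100, 100, 0.5)
        lx, ly = g.extent_mm
        assert lx == ly == pytest.approx(49.5)

    def test_refinement_quadruples_elements(self):
        coarse = G.make_sheet(100, 100, 0.5)
        fine = G.make_sheet(200, 200, 0.25)
        assert fine.extent_mm[0] == pytest.approx(coarse.extent_mm[0], abs=0.25)
        assert fine.labels.size == 199 ** 2   # ~4x the coarse 99^2
        assert coarse.labels.size == 99 ** 2

    @pytest.mark.parametrize("nx,ny,h", [(2, 5, 0.5), (5, 2, 0.5), (5, 5, 0.0), (5, 5, -1.0)])
    def test_invalid_dimensions_rejected(self, nx, ny, h):
        with pytest.raises(ValueError):
            G.make_sheet(nx, ny, h)

    def test_two_region_halves_are_disjoint_and_cover(self):
        g = G.make_two_region_sheet(21, 11, 0.5)
        law, raw = g.named_regions["LAW"], g.named_regions["RAW"]
        assert not np.any(law & raw)
        assert np.all(law | raw)


class TestFibrosis:
    def test_exact_counts_uiv_law(self):
        # |LAW| must be exactly 1000 elements: 101 x 21 nodes -> 100 x 20
        g = G.make_two_region_sheet(101, 21, 0.5)
        assert int(g.named_regions["LAW"].sum()) == 1000
        out = G.apply_fibrosis(g, G.utah_iv_preset(seed=7))
        n_fib = int(np.sum((out.labels != G.WORKING) & g.named_regions["LAW"]))
        assert n_fib == 390

    def test_exact_counts_uii_raw_and_nonconductive_split(self):
        g = G.make_two_region_sheet(81, 51, 0.5)
        n_raw = int(g.named_regions["RAW"].sum())
        assert n_raw == 2000
        out = G.apply_fibrosis(g, G.utah_ii_preset(seed=1))
        raw = g.named_regions["RAW"]
        n_fib = int(np.sum((out.labels != G.WORKING) & raw))
        n_nc = int(np.sum((out.labels == G.NONCONDUCTIVE) & raw))
        assert n_fib == 100
        assert n_nc == 50
        assert np.all(out.sigma[(out.labels == G.NONCONDUCTIVE)] == G.NONCONDUCTIVE_SIGMA)

    def test_zero_fraction_leaves_geometry_unchanged(self):
        g = G.make_two_region_sheet(21, 21, 0.5)
        out = G.apply_fibrosis(
            g, G.FibrosisPreset("custom", {"LAW": 0.0, "RAW": 0.0}, seed=0)
        )
        np.testing.assert_array_equal(out.labels, g.labels)
        np.testing.assert_array_equal(out.sigma, g.sigma)

    def test_deterministic_given_seed(self):
        g = G.make_two_region_sheet(41, 41, 0.5)
        a = G.apply_fibrosis(g, G.utah_iv_preset(seed=3))
        b = G.apply_fibrosis(g, G.utah_iv_preset(seed=3))
        c = G.apply_fibrosis(g, G.utah_iv_preset(seed=4))
        np.testing.assert_array_equal(a.labels, b.labels)
        assert np.any(a.labels != c.labels)

    def test_unknown_region_and_bad_fraction(self):
        g = G.make_sheet(11, 11, 0.5)
        with pytest.raises(KeyError):
            G.apply_fibrosis(g, G.FibrosisPreset("x", {"nope": 0.1}))
        with pytest.raises(ValueError):
            G.FibrosisPreset("x", {"LAW": 1.5})


class TestSegments:
    def test_single_segment_covers_domain(self):
        g = G.partition_segments(G.make_sheet(11, 11, 0.5), 1)
        assert set(np.unique(g.segments)) == {0}

    def test_k2_on_even_sheet(self):
        g = G.partition_segments(G.make_sheet(101, 101, 0.5), 2)
        counts = np.bincount(g.segments.ravel())
        assert len(counts) == 4
        assert counts.sum() == 100 * 100
        assert np.all(np.abs(counts - 2500) <= 100)  # rounding at block edges

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_partition_property(self, k):
        g = G.partition_segments(G.make_sheet(34, 27, 0.5), k)
        seen = np.bincount(g.segments.ravel(), minlength=k * k)
        assert seen.sum() == g.labels.size          # exhaustive
        assert np.all(seen > 0)                     # no empty segment


class TestPacingSites:
    def test_grid_on_5cm_sheet(self):
        g = G.make_sheet(101, 101, 0.5)  # 50 x 50 mm
        sites = G.make_pacing_sites(g, d_mm=10.0, margin_mm=5.0)
        assert len(sites) == 25  # positions 5,15,25,35,45 on both axes

    def test_interior_grid_when_margin_trims_edge(self):
        g = G.make_sheet(100, 100, 0.5)  # 49.5 mm
        sites = G.make_pacing_sites(g, d_mm=10.0, margin_mm=5.0)
        assert len(sites) == 16

    def test_spacing_equal_to_edge_gives_one_site(self):
        g = G.make_sheet(41, 41, 0.5)  # 20 mm
        sites = G.make_pacing_sites(g, d_mm=20.0, margin_mm=10.0)
        assert len(sites) == 1

    def test_too_small_spacing_rejected(self):
        g = G.make_sheet(21, 21, 0.5)
        with pytest.raises(ValueError):
            G.make_pacing_sites(g, d_mm=0.5)

    def test_sites_land_on_conductive_tissue_despite_fibrosis(self):
        g = G.make_two_region_sheet(101, 101, 0.5)
        g = G.apply_fibrosis(
            g, G.FibrosisPreset("dense", {"LAW": 0.9, "RAW": 0.9}, seed=11)
        )
        sites = G.make_pacing_sites(g, d_mm=10.0, margin_mm=5.0)
        cond = g.conductive_nodes()
        assert len(sites) + len(sites.dropped) >= 16
        for i, j in sites.sites:
            assert cond[i, j]


class TestGeodesicDistance:
    def test_identity(self):
        g = G.make_sheet(21, 21, 0.5)
        assert G.geodesic_distance(g, (3.0, 3.0), (3.0, 3.0)) == 0.0

    def test_straight_line_on_open_sheet(self):
        g = G.make_sheet(101, 31, 0.5)
        d = G.geodesic_distance(g, (10.0, 7.0), (40.0, 7.0))
        assert d == pytest.approx(30.0, abs=g.h)

    def test_path_through_gap_matches_graph_oracle(self):
        g = G.make_sheet(41, 41, 0.5)
        # full-width bar, 2 elements thick, with a 2 mm gap
        g.labels[19:21, :] = G.NONCONDUCTIVE
        g.sigma[19:21, :] = G.NONCONDUCTIVE_SIGMA
        g.labels[19:21, 18:22] = G.WORKING
        g.sigma[19:21, 18:22] = G.DEFAULT_SIGMA
        a, b = (5.0, 2.0), (5.0, 18.0)
        d = G.geodesic_distance(g, a, b)
        # independent oracle: networkx shortest path on the same node rule
        cond = g.conductive_nodes()
        graph = nx.Graph()
        ny, nx_ = cond.shape
        for i in range(ny):
            for j in range(nx_):
                if not cond[i, j]:
                    continue
                for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx_ and cond[ii, jj]:
                        w = g.h * (2 ** 0.5 if di and dj else 1.0)
                        graph.add_edge((i, j), (ii, jj), weight=w)
        expected = nx.shortest_path_length(
            graph, g.nearest_node(a), g.nearest_node(b), weight="weight"
        )
        assert d == pytest.approx(expected, rel=1e-9)
        assert d > 16.0  # clearly longer than the 16 mm straight line

    def test_disconnected_endpoints_signaled(self):
        g = G.make_sheet(21, 21, 0.5)
        g.labels[9:11, :] = G.NONCONDUCTIVE
        g.sigma[9:11, :] = G.NONCONDUCTIVE_SIGMA
        with pytest.raises(ValueError, match="disconnected"):
            G.geodesic_distance(g, (5.0, 2.0), (5.0, 8.0))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(0)
        g = G.make_sheet(31, 31, 0.5)
        pts = [(rng.uniform(0, 15), rng.uniform(0, 15)) for _ in range(6)]
        for a, b, c in zip(pts, pts[2:], pts[4:]):
            dab = G.geodesic_distance(g, a, b)
            dba = G.geodesic_distance(g, b, a)
            dac = G.geodesic_distance(g, a, c)
            dcb = G.geodesic_distance(g, c, b)
            assert dab == pytest.approx(dba, rel=1e-12)
            assert dab <= dac + dcb + 1e-9
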