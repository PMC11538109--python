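import numpy as np
import pytest

from conftest import render_tubes
from mpmtools.morse_graph import (
    EmbeddedGraph,
    MorseParams,
    extract_morse_skeleton,
    prune_and_filter,
    smooth_branches,
)
from mpmtools.synthetic_fixtures import VesselFixtureSpec, make_vessel_fixture, true_network_stats


def path_graph(points, pixel_size_um=1.0):
    g = EmbeddedGraph(pixel_size_um=pixel_size_um)
    for i, (x, y) in enumerate(points):
        g.add_vertex(i, x, y)
    for i in range(len(points) - 1):
        g.add_edge(i, i + 1, np.array([points[i], points[i + 1]], float))
    return g


class TestExtraction:
    def test_constant_image_gives_empty_graph(self):
        g = extract_morse_skeleton(np.full((64, 64), 3.0), MorseParams())
        assert g.n_edges == 0

    def test_single_straight_tube_recovered_within_5pc(self):
        img = render_tubes([((28, 128), (228, 128))])
        g = extract_morse_skeleton(img, MorseParams(), pixel_size_um=1.0)
        g = smooth_branches(prune_and_filter(g, MorseParams()), 5)
        assert len(g.branches()) == 1
        assert g.total_length_um() == pytest.approx(200.0, rel=0.05)

    def test_crossing_tubes_form_a_junction(self):
        img = render_tubes([((40, 40), (216, 216)), ((40, 216), (216, 40))])
        g = extract_morse_skeleton(img, MorseParams(), pixel_size_um=1.0)
        g = prune_and_filter(g, MorseParams())
        degrees = dict(g.graph.degree())
        assert max(degrees.values()) >= 3          # at least one junction vertex
        leaf_branches = [b for b in g.branches()
                         if g.graph.degree(b["nodes"][0]) == 1 or g.graph.degree(b["nodes"][1]) == 1]
        assert len(leaf_branches) == 4

    @pytest.mark.parametrize("seed,n_branches", [(21, 3), (45, 2)])
    def test_matches_thinning_skeleton_on_clean_fixture(self, seed, n_branches):
        from skimage.morphology import skeletonize

        spec = VesselFixtureSpec(n_branches=n_branches, snr=0, seed=seed, image_size=256,
                                 branch_length_um=(60, 150), pixel_size_um=2.0)
        img, truth, mask = make_vessel_fixture(spec)
        g = smooth_branches(prune_and_filter(extract_morse_skeleton(img, MorseParams(), 2.0), MorseParams()), 5)
        skel = skeletonize(mask)
        # corrected digital-curve length (Vossepoel-Smeulders step weights):
        # the naive 1/sqrt2 step sum overestimates oblique curves by up to 8%
        ys, xs = np.nonzero(skel)
        coords = set(zip(ys.tolist(), xs.tolist()))
        n_orth = n_diag = 0
        for y, x in coords:
            for dy, dx in ((0, 1), (1, 0)):
                n_orth += (y + dy, x + dx) in coords
            for dy, dx in ((1, 1), (1, -1)):
                n_diag += (y + dy, x + dx) in coords
        skel_um = (0.948 * n_orth + 1.340 * n_diag) * 2.0
        assert g.total_length_um() == pytest.approx(skel_um, rel=0.05)


class TestPruning:
    def make_network_with_spur(self, spur_len_um):
        # T-network: long bar with a spur hanging off the middle
        g = EmbeddedGraph(pixel_size_um=1.0)
        g.add_vertex(0, 0, 0)
        g.add_vertex(1, 100, 0)
        g.add_vertex(2, 200, 0)
        g.add_vertex(3, 100, spur_len_um)
        g.add_edge(0, 1, np.array([[0, 0], [100, 0]], float))
        g.add_edge(1, 2, np.array([[100, 0], [200, 0]], float))
        g.add_edge(1, 3, np.array([[100, 0], [100, spur_len_um]], float))
        return g

    def test_short_leaf_removed_long_kept(self):
        pruned = prune_and_filter(self.make_network_with_spur(8.0), MorseParams(min_branch_um=10))
        assert pruned.graph.number_of_nodes() == 2      # spur gone, chain merged
        kept = prune_and_filter(self.make_network_with_spur(12.0), MorseParams(min_branch_um=10))
        assert kept.graph.number_of_edges() == 3

    def test_everything_short_gives_empty_graph(self):
        g = path_graph([(0, 0), (4, 0)])
        assert prune_and_filter(g, MorseParams(min_branch_um=10)).n_edges == 0

    def test_remove_disconnected_keeps_largest_by_length(self):
        g = path_graph([(0, 0), (250, 0), (500, 0)])
        g.add_vertex(10, 0, 50)
        g.add_vertex(11, 40, 50)
        g.add_edge(10, 11, np.array([[0, 50], [40, 50]], float))
        out = prune_and_filter(g, MorseParams(min_branch_um=10, remove_disconnected=True))
        assert out.total_length_um() == pytest.approx(500.0)

    def test_pruning_never_increases_length(self):
        g = self.make_network_with_spur(8.0)
        assert prune_and_filter(g, MorseParams()).total_length_um() <= g.total_length_um()


class TestSmoothing:
    def test_straight_branch_unchanged(self):
        pts = [(float(i), 0.0) for i in range(11)]
        g = path_graph(pts)
        sm = smooth_branches(g, 5)
        assert sm.total_length_um() == pytest.approx(10.0, abs=1e-9)

    def test_staircase_shortens_toward_chord(self):
        pts = []
        x = y = 0
        pts.append((0.0, 0.0))
        for _ in range(10):
            x += 1
            pts.append((float(x), float(y)))
            y += 1
            pts.append((float(x), float(y)))
        g = EmbeddedGraph(pixel_size_um=1.0)
        g.add_vertex(0, 0, 0)
        g.add_vertex(1, 10, 10)
        g.add_edge(0, 1, np.array(pts))
        raw = g.total_length_um()
        assert raw == pytest.approx(20.0)
        sm = smooth_branches(g, 5)
        assert 10 * np.sqrt(2) <= sm.total_length_um() < 20.0

    def test_endpoints_fixed_and_topology_unchanged(self):
        img = render_tubes([((40, 40), (216, 216)), ((40, 216), (216, 40))])
        g = prune_and_filter(extract_morse_skeleton(img, MorseParams(), 1.0), MorseParams())
        sm = smooth_branches(g, 5)
        assert sm.graph.number_of_edges() == g.graph.number_of_edges()
        for n, d in g.graph.nodes(data=True):
            assert sm.graph.nodes[n]["pos"] == d["pos"]
        for (u, v, d_old), (_, _, d_new) in zip(
            g.graph.edges(data=True), sm.graph.edges(data=True)
        ):
            np.testing.assert_allclose(d_old["polyline"][0], d_new["polyline"][0])
            np.testing.assert_allclose(d_old["polyline"][-1], d_new["polyline"][-1])
        assert len(sm.branches()) <= len(g.branches())

    def test_smoothed_length_at_least_chord(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(0, 1, size=(30, 2)), axis=0)
        g = EmbeddedGraph(pixel_size_um=1.0)
        g.add_vertex(0, *pts[0])
        g.add_vertex(1, *pts[-1])
        g.add_edge(0, 1, pts)
        sm = smooth_branches(g, 5)
        chord = float(np.hypot(*(pts[-1] - pts[0])))
        assert sm.total_length_um() >= chord - 1e-9

    def test_window_validation(self):
        g = path_graph([(0, 0), (1, 0)])
        with pytest.raises(ValueError):
            smooth_branches(g, 4)


class TestExport:
    def test_graphml_and_csv_round_trip_lengths(self, tmp_path):
        import csv

        import networkx as nx

        g = path_graph([(0.0, 0.0), (3.0, 4.0), (6.0, 8.0)], pixel_size_um=2.0)
        from mpmtools.morse_graph import export_graph

        gml = tmp_path / "net.graphml"
        ecsv = tmp_path / "edges.csv"
        export_graph(g, gml, ecsv)
        back = nx.read_graphml(gml)
        assert back.number_of_edges() == 2
        lengths = sorted(float(d["length_um"]) for _, _, d in back.edges(data=True))
        assert lengths == pytest.approx([10.0, 10.0])
        with open(ecsv) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 2
        assert float(rows[0]["length_um"]) == pytest.approx(10.0)
        assert ";" in rows[0]["polyline"]


class TestEndToEndRecovery:
    def test_quick_noisy_recovery(self):
        from mpmtools.vessel_seg import ProbabilityMap, refine_probability_map
        from mpmtools.topology_stats import network_statistics

        hits = 0
        for seed in range(5):
            spec = VesselFixtureSpec(n_branches=5 + 2 * seed, snr=5, seed=300 + seed,
                                     image_size=256, branch_length_um=(30, 150), pixel_size_um=2.5)
            img, truth, _ = make_vessel_fixture(spec)
            ts = true_network_stats(truth)
            ref = refine_probability_map(ProbabilityMap(image=np.clip(img, 0, 1)))
            g = smooth_branches(prune_and_filter(extract_morse_skeleton(ref, MorseParams(), 2.5), MorseParams()), 5)
            stats, _ = network_statistics(g)
            if abs(stats.branch_count - ts["branch_count"]) <= 1 and \
               abs(stats.total_length_um - ts["total_length_um"]) <= 0.10 * ts["total_length_um"]:
                hits += 1
        assert hits >= 4
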