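import networkx as nx
import numpy as np
import pytest

from mpmtools.errors import EmptyInputError
from mpmtools.morse_graph import EmbeddedGraph
from mpmtools.topology_stats import (
    Barcode,
    choose_root,
    compute_barcode,
    network_statistics,
    shortest_path_tree,
    summarize_network,
)


def weighted(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, length_um=float(w))
    return g


def brute_force_barcode(tree, root):
    """Independent elder-rule oracle: claim paths leaf-to-root in order of
    decreasing depth (ties to the smaller leaf id); a bar dies where its
    path first meets a claimed vertex."""
    dist = nx.single_source_dijkstra_path_length(tree, root, weight="length_um")
    paths = nx.single_source_dijkstra_path(tree, root, weight="length_um")
    leaves = [v for v in tree.nodes if tree.degree(v) == 1 and v != root]
    claimed = set()
    bars = []
    for leaf in sorted(leaves, key=lambda v: (-dist[v], v)):
        path = list(reversed(paths[leaf]))      # leaf ... root
        death = 0.0
        for v in path:
            if v in claimed:
                death = -dist[v]
                break
            claimed.add(v)
        bars.append((-dist[leaf], death))
    return sorted(bars)


class TestChooseRoot:
    def test_path_center_with_tie_to_lower_id(self):
        g = weighted([(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        assert choose_root(g) == 1

    def test_star_hub(self):
        g = weighted([(9, 1, 1), (9, 2, 1), (9, 3, 1)])
        assert choose_root(g) == 9

    def test_uniform_cycle_lowest_id(self):
        g = weighted([(i, (i + 1) % 6, 1) for i in range(6)])
        assert choose_root(g) == 0

    def test_empty_graph_rejected(self):
        with pytest.raises(EmptyInputError):
            choose_root(nx.Graph())


class TestShortestPathTree:
    def test_tree_input_returned_identically(self):
        g = weighted([(0, 1, 2), (1, 2, 3), (1, 3, 1)])
        t = shortest_path_tree(g, 0)
        assert set(t.edges) == set(g.edges)

    def test_triangle_drops_far_edge(self):
        g = weighted([(0, 1, 1), (0, 2, 1), (1, 2, 1)])
        t = shortest_path_tree(g, 0)
        assert set(map(frozenset, t.edges)) == {frozenset({0, 1}), frozenset({0, 2})}

    def test_cycle_tree_has_n_minus_one_edges(self):
        g = weighted([(i, (i + 1) % 8, 1) for i in range(8)])
        t = shortest_path_tree(g, 0)
        assert t.number_of_edges() == 7
        assert sum(d["length_um"] for _, _, d in t.edges(data=True)) == pytest.approx(7.0)


class TestBarcode:
    def test_path_rooted_at_end(self):
        t = weighted([(0, 1, 4), (1, 2, 6)])
        bc = compute_barcode(t, 0)
        assert len(bc) == 1
        assert (bc.bars[0].birth, bc.bars[0].death) == (-10.0, 0.0)

    def test_star_persistences_are_arm_lengths(self):
        t = weighted([(0, 1, 10), (0, 2, 6), (0, 3, 4)])
        bc = compute_barcode(t, 0)
        assert sorted(bc.persistences) == [4.0, 6.0, 10.0]

    def test_t_shape_elder_rule(self):
        # root - 5um stem - junction with arms 10 and 3
        t = weighted([(0, 1, 5), (1, 2, 10), (1, 3, 3)])
        bc = compute_barcode(t, 0)
        bars = sorted((b.birth, b.death) for b in bc.bars)
        assert bars == [(-15.0, 0.0), (-8.0, -5.0)]
        assert sorted(bc.persistences) == [3.0, 15.0]
        assert bc.persistences.sum() == pytest.approx(18.0)

    @pytest.mark.parametrize("n,seed", [(12, 0), (25, 1), (40, 2), (60, 3)])
    def test_conservation_and_leaf_count_on_random_trees(self, n, seed):
        rng = np.random.default_rng(seed)
        t = nx.random_labeled_tree(n, seed=seed)
        for u, v in t.edges:
            t.edges[u, v]["length_um"] = float(rng.uniform(0.5, 30.0))
        root = choose_root(t)
        bc = compute_barcode(t, root)
        total = sum(d["length_um"] for _, _, d in t.edges(data=True))
        assert bc.persistences.sum() == pytest.approx(total, rel=1e-9)
        n_leaves = sum(1 for v in t.nodes if t.degree(v) == 1 and v != root)
        assert len(bc) == n_leaves

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        t = nx.random_labeled_tree(int(rng.integers(4, 14)), seed=seed + 100)
        for u, v in t.edges:
            t.edges[u, v]["length_um"] = float(rng.integers(1, 20))
        root = choose_root(t)
        bc = compute_barcode(t, root)
        got = sorted((b.birth, b.death) for b in bc.bars)
        assert got == pytest.approx(brute_force_barcode(t, root))

    def test_invariant_under_rigid_motion(self):
        def embed(theta, tx, ty):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            pts = {0: (0, 0), 1: (10, 0), 2: (10, 7), 3: (10, -4)}
            g = EmbeddedGraph(pixel_size_um=1.0)
            for k, p in pts.items():
                q = R @ np.array(p) + (tx, ty)
                g.add_vertex(k, *q)
            for u, v in [(0, 1), (1, 2), (1, 3)]:
                pu = R @ np.array(pts[u]) + (tx, ty)
                pv = R @ np.array(pts[v]) + (tx, ty)
                g.add_edge(u, v, np.array([pu, pv]))
            return g

        stats1, bc1 = network_statistics(embed(0.0, 0, 0))
        stats2, bc2 = network_statistics(embed(1.1, 40, -22))
        np.testing.assert_allclose(sorted(bc1.persistences), sorted(bc2.persistences), rtol=1e-9)

    def test_cyclic_graph_tree_length_bounded_by_graph_length(self):
        g = weighted([(0, 1, 3), (1, 2, 4), (2, 3, 3), (3, 0, 4), (1, 3, 2)])
        root = choose_root(g)
        t = shortest_path_tree(g, root)
        bc = compute_barcode(t, root)
        tree_len = sum(d["length_um"] for _, _, d in t.edges(data=True))
        graph_len = sum(d["length_um"] for _, _, d in g.edges(data=True))
        assert bc.persistences.sum() == pytest.approx(tree_len, rel=1e-9)
        assert tree_len <= graph_len


class TestSummarize:
    def test_t_shape_summary(self):
        t = weighted([(0, 1, 5), (1, 2, 10), (1, 3, 3)])
        bc = compute_barcode(t, 0)
        stats = summarize_network(bc, t)
        assert stats.branch_count == 2
        assert stats.tree_length_um == pytest.approx(18.0)
        assert stats.total_length_um == pytest.approx(18.0)
        assert stats.mean_branch_length_um == pytest.approx(9.0)

    def test_single_path(self):
        t = weighted([(0, 1, 10)])
        bc = compute_barcode(t, 0)
        stats = summarize_network(bc, t)
        assert (stats.branch_count, stats.total_length_um, stats.mean_branch_length_um) == (1, 10.0, 10.0)

    def test_empty_graph_zeroed(self):
        stats = summarize_network(Barcode(bars=[], root=-1), nx.Graph())
        assert (stats.branch_count, stats.total_length_um, stats.mean_branch_length_um) == (0, 0.0, 0.0)
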