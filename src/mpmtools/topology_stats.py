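"""Branch decomposition of vessel networks via persistent homology.

The network is filtered by ``f(x) = -d(x, r)``, the negative geodesic
distance to a root ``r`` chosen at the network centre.  Sub-level sets
grow from the leaves toward the root; each leaf births a bar at minus
its distance to the root, and when two branches merge the bar of the
shorter branch dies (elder rule).  A bar's persistence ``d - b`` is the
length of the branch it represents, so for a tree the persistences sum
exactly to the total tree length.

Cyclic networks are first reduced to their shortest-path tree from the
root, which makes the barcode a genuine branch decomposition.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from mpmtools.errors import EmptyInputError
from mpmtools.morse_graph import EmbeddedGraph, graph_to_networkx_simple


@dataclass
class Bar:
    birth: float
    death: float
    leaf: int          # id of the leaf that births this bar

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class Barcode:
    """Multiset of [birth, death] intervals; persistences are branch lengths in um."""

    bars: list[Bar]
    root: int

    @property
    def persistences(self) -> np.ndarray:
        return np.array([b.persistence for b in self.bars], dtype=float)

    def __len__(self) -> int:
        return len(self.bars)


@dataclass
class NetworkStats:
    """Aggregate microvessel statistics for one network.

    ``total_length_um`` is the summed length of all *graph* edges;
    ``tree_length_um`` is the shortest-path-tree length (equal for
    acyclic networks, smaller when the graph has cycles).
    """

    branch_count: int
    total_length_um: float
    mean_branch_length_um: float
    tree_length_um: float = 0.0


def _as_weighted(graph) -> nx.Graph:
    if isinstance(graph, EmbeddedGraph):
        return graph_to_networkx_simple(graph)
    return graph


def _largest_component(g: nx.Graph) -> set:
    comps = list(nx.connected_components(g))
    if not comps:
        raise EmptyInputError("graph has no vertices")

    def total(c):
        return sum(d["length_um"] for u, v, d in g.edges(c, data=True))

    return max(comps, key=lambda c: (total(c), len(c), -min(c)))


def _dijkstra(g: nx.Graph, root) -> tuple[dict, dict]:
    """Length-weighted shortest paths with deterministic tie-breaking:
    among equal-distance routes the smallest predecessor id wins."""
    dist = {root: 0.0}
    pred: dict = {root: None}
    heap = [(0.0, -1, root)]
    done = set()
    while heap:
        d, p, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if p >= 0:
            pred[u] = p
        for v in g.neighbors(u):
            nd = d + g.edges[u, v]["length_um"]
            if v not in done and (v not in dist or nd < dist[v] - 1e-12):
                dist[v] = nd
                heapq.heappush(heap, (nd, u, v))
            elif v not in done and abs(nd - dist[v]) <= 1e-12:
                heapq.heappush(heap, (nd, u, v))   # tie: heap order prefers smaller pred id
    return dist, pred


def choose_root(graph) -> int:
    """Centre of the network: the vertex of minimum eccentricity (max
    geodesic distance to any other vertex) in the largest component,
    ties broken by smallest vertex id."""
    g = _as_weighted(graph)
    if g.number_of_nodes() == 0:
        raise EmptyInputError("cannot choose a root of an empty graph")
    comp = _largest_component(g)
    sub = g.subgraph(comp)
    best = None
    for v in sorted(sub.nodes):
        dist, _ = _dijkstra(sub, v)
        ecc = max(dist.values())
        if best is None or ecc < best[0] - 1e-12:
            best = (ecc, v)
    return best[1]


def shortest_path_tree(graph, root) -> nx.Graph:
    """Geodesic shortest-path tree of the root's component.

    Each non-root vertex keeps its predecessor edge; equal-length
    alternatives resolve to the smallest predecessor id.
    """
    g = _as_weighted(graph)
    if root not in g:
        raise EmptyInputError(f"root {root} not in graph")
    dist, pred = _dijkstra(g, root)
    tree = nx.Graph()
    for v, d in dist.items():
        tree.add_node(v, dist=d)
    for v, p in pred.items():
        if p is not None:
            tree.add_edge(p, v, length_um=dist[v] - dist[p])
    return tree


def compute_barcode(tree: nx.Graph, root) -> Barcode:
    """Elder-rule barcode of the sublevel filtration f = -dist(., root).

    One bar per leaf; at every merge vertex the bars of all but the
    deepest-reaching sub-branch die (ties broken by smaller leaf id);
    the globally deepest leaf's bar dies at 0, the root.
    """
    if root not in tree:
        raise EmptyInputError(f"root {root} not in tree")
    if tree.number_of_nodes() == 1:
        return Barcode(bars=[], root=root)

    dist = {root: 0.0}
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in tree.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + tree.edges[u, v]["length_um"]
                parent[v] = u
                order.append(v)
                stack.append(v)

    children: dict = {v: [] for v in dist}
    for v, p in parent.items():
        if p is not None:
            children[p].append(v)

    # champion of each subtree: the leaf of maximal depth, ties -> smaller id
    champion: dict = {}
    bars: list[Bar] = []
    for v in reversed(order):           # children before parents
        if not children[v]:
            champion[v] = v
            continue
        cands = [champion[c] for c in children[v]]
        winner = max(cands, key=lambda leaf: (dist[leaf], -leaf))
        for leaf in cands:
            if leaf != winner:
                bars.append(Bar(birth=-dist[leaf], death=-dist[v], leaf=leaf))
        champion[v] = winner
    top = champion[root]
    bars.append(Bar(birth=-dist[top], death=0.0, leaf=top))
    bars.sort(key=lambda b: (b.birth, b.leaf))
    return Barcode(bars=bars, root=root)


def summarize_network(barcode: Barcode, graph) -> NetworkStats:
    """Branch count, total network length and mean branch length.

    ``branch_count`` is the number of bars; ``mean_branch_length_um``
    the mean bar persistence; ``total_length_um`` sums all graph edges
    (for cyclic networks this exceeds the tree length, which is also
    reported).
    """
    g = _as_weighted(graph)
    total = float(sum(d["length_um"] for _, _, d in g.edges(data=True)))
    if len(barcode) == 0:
        return NetworkStats(branch_count=0, total_length_um=total, mean_branch_length_um=0.0, tree_length_um=0.0)
    pers = barcode.persistences
    return NetworkStats(
        branch_count=len(barcode),
        total_length_um=total,
        mean_branch_length_um=float(pers.mean()),
        tree_length_um=float(pers.sum()),
    )


def network_statistics(graph) -> tuple[NetworkStats, Barcode]:
    """Convenience chain: root -> shortest-path tree -> barcode -> stats.

    The barcode is computed on the largest component; totals cover the
    whole graph.
    """
    g = _as_weighted(graph)
    if g.number_of_nodes() == 0:
        return NetworkStats(0, 0.0, 0.0, 0.0), Barcode(bars=[], root=-1)
    root = choose_root(g)
    tree = shortest_path_tree(g, root)
    barcode = compute_barcode(tree, root)
    stats = summarize_network(barcode, g)
    return stats, barcode
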