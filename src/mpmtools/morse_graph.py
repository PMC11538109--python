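"""Embedded vessel-network graphs via discrete-Morse ridge extraction.

A grayscale vesselness image is viewed as a terrain: pixel intensity is
height, vessels are mountain ridges connecting peaks (bright cells).
The extractor walks the terrain top-down with a union-find sweep:

1. every pixel is visited in decreasing (intensity, index) order — the
   index tie-break makes the order a strict total order;
2. a pixel whose processed 8-neighbourhood is empty is a *local
   maximum* (a new peak); a pixel joining two or more existing
   components is a *saddle* and records a merge event with persistence
   ``f(dying peak) - f(saddle)``;
3. each merge event contributes a ridge arc: the steepest-ascent path
   from the saddle into both merging components;
4. low-persistence (peak, saddle) pairs — noise — are *cancelled* in
   increasing persistence order: a spur peak disappears with its arc,
   and a chain peak is dissolved by splicing its two arcs together, so
   ridge geometry survives simplification.

The resulting :class:`EmbeddedGraph` holds polyline edges in pixel
coordinates with physical lengths.  ``prune_and_filter`` removes leaf
branches shorter than 10 um (iterated to a fixed point) and optionally
non-largest components; ``smooth_branches`` relaxes the staircase
geometry of grid-aligned arcs with a centred moving average.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from mpmtools.errors import EmptyInputError


@dataclass
class MorseParams:
    """Parameters for skeleton extraction and simplification.

    ``persistence_cutoff`` is in intensity units; ``None`` selects
    ``max(2 * sigma_MAD, 0.005 * max intensity)`` where ``sigma_MAD`` is
    the robust noise scale ``1.4826 * median(|I - median(I)|)``.
    ``smooth_sigma`` is a Gaussian pre-smoothing of the intensity field
    before ridge extraction — the counterpart of the peak-merging
    smoothing step the ridge-extraction method relies on to keep noise
    peaks from fragmenting ridges; 0 disables it.
    ``support_floor`` restricts the Morse domain to pixels with
    intensity strictly above it (default 0): the exact-zero background
    of a masked vesselness image is "no data", and excluding it keeps
    disjoint network pieces from being joined by arcs wandering across
    empty background.  Set to ``-numpy.inf`` to use the full frame.
    """

    persistence_cutoff: float | None = None
    min_branch_um: float = 10.0
    smoothing_window: int = 5
    remove_disconnected: bool = False
    smooth_sigma: float = 1.0
    support_floor: float = 0.0


def _polyline_length(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(np.asarray(poly, dtype=float), axis=0).T)))


@dataclass
class EmbeddedGraph:
    """Planar geometric multigraph of a vessel network.

    Nodes carry ``pos`` = (x, y) pixel coordinates; edges carry a
    ``polyline`` — an (m, 2) array of (x, y) points whose endpoints
    coincide with the node positions — and ``length_px``.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    pixel_size_um: float = 1.0

    def add_vertex(self, vid: int, x: float, y: float) -> None:
        self.graph.add_node(vid, pos=(float(x), float(y)))

    def add_edge(self, u: int, v: int, polyline: np.ndarray) -> None:
        poly = np.asarray(polyline, dtype=float)
        self.graph.add_edge(u, v, polyline=poly, length_px=_polyline_length(poly))

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_length_um(self, u: int, v: int, k: int) -> float:
        return self.graph.edges[u, v, k]["length_px"] * self.pixel_size_um

    def total_length_um(self) -> float:
        return float(sum(d["length_px"] for _, _, d in self.graph.edges(data=True)) * self.pixel_size_um)

    def copy(self) -> "EmbeddedGraph":
        return EmbeddedGraph(graph=self.graph.copy(), pixel_size_um=self.pixel_size_um)

    def branches(self) -> list[dict]:
        """Branch decomposition: maximal paths between junctions/leaves.

        Returns one dict per branch with keys ``nodes`` (endpoint ids),
        ``edges`` (list of (u, v, k)), ``length_um`` and ``polyline``.
        Isolated cycles (all vertices degree 2) yield one closed branch.
        """
        g = self.graph
        branches = []
        visited: set[tuple] = set()

        def edge_key(u, v, k):
            return (min(u, v), max(u, v), k)

        def walk(start, u, v, k):
            """Follow a chain of degree-2 nodes starting along edge (u,v,k)."""
            nodes = [u]
            edges = []
            poly_parts = []
            cur_u, cur_v, cur_k = u, v, k
            while True:
                visited.add(edge_key(cur_u, cur_v, cur_k))
                edges.append((cur_u, cur_v, cur_k))
                d = g.edges[cur_u, cur_v, cur_k]
                poly = d["polyline"]
                if len(poly) and tuple(poly[0]) != g.nodes[cur_u]["pos"]:
                    poly = poly[::-1]
                poly_parts.append(poly)
                nodes.append(cur_v)
                if g.degree(cur_v) != 2 or cur_v == start:
                    break
                nxt = None
                for nu, nv, nk in g.edges(cur_v, keys=True):
                    if edge_key(nu, nv, nk) not in visited:
                        nxt = (nu, nv, nk)
                        break
                if nxt is None:
                    break
                cur_u, cur_v, cur_k = nxt
            full = np.vstack([p if i == 0 else p[1:] for i, p in enumerate(poly_parts) if len(p)]) if poly_parts else np.empty((0, 2))
            return {
                "nodes": (nodes[0], nodes[-1]),
                "edges": edges,
                "length_um": _polyline_length(full) * self.pixel_size_um,
                "polyline": full,
            }

        anchors = [n for n in g.nodes if g.degree(n) != 2]
        for a in anchors:
            for u, v, k in g.edges(a, keys=True):
                if edge_key(u, v, k) not in visited:
                    start_from = a if u == a else a
                    other = v if u == a else u
                    branches.append(walk(a, a, other, k))
        # isolated cycles: all remaining edges have degree-2 endpoints
        for u, v, k in list(g.edges(keys=True)):
            if edge_key(u, v, k) not in visited:
                branches.append(walk(u, u, v, k))
        return branches

    def merge_degree2_chains(self) -> "EmbeddedGraph":
        """Collapse every chain of degree-2 vertices into a single edge."""
        out = EmbeddedGraph(pixel_size_um=self.pixel_size_um)
        for br in self.branches():
            u, v = br["nodes"]
            for n in (u, v):
                if n not in out.graph:
                    out.add_vertex(n, *self.graph.nodes[n]["pos"])
            out.add_edge(u, v, br["polyline"])
        for n in self.graph.nodes:   # keep isolated vertices out; nothing to add
            pass
        return out


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbors(idx: int, h: int, w: int) -> list[int]:
    r, c = divmod(idx, w)
    out = []
    for dr, dc in _NEIGH:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            out.append(rr * w + cc)
    return out


def default_persistence_cutoff(image: np.ndarray) -> float:
    """2x the MAD-based robust noise sigma, floored at 0.5% of the max."""
    img = np.asarray(image, dtype=np.float64)
    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - med))
    return float(max(2.0 * sigma, 0.005 * img.max(), 1e-12))


def extract_morse_skeleton(vesselness, params: MorseParams | None = None, pixel_size_um: float = 1.0) -> EmbeddedGraph:
    """Extract the ridge ("Morse skeleton") graph of a 2D vesselness image.

    ``vesselness`` is a 2D array or an object with an ``image``
    attribute (e.g. a probability map).  Vertices sit on retained local
    maxima; polyline edges follow steepest-ascent ridge paths through
    the saddles connecting them.  (peak, saddle) pairs with persistence
    below the cutoff are cancelled; a constant image yields an empty
    graph.
    """
    params = params or MorseParams()
    img2d = np.asarray(getattr(vesselness, "image", vesselness), dtype=np.float64)
    if img2d.ndim != 2:
        raise EmptyInputError("vesselness must be a 2D image")
    if params.smooth_sigma > 0:
        img2d = ndi.gaussian_filter(img2d, params.smooth_sigma)
    h, w = img2d.shape
    n = h * w
    flat = img2d.ravel()
    cutoff = params.persistence_cutoff if params.persistence_cutoff is not None else default_persistence_cutoff(img2d)

    # strict total order: descending intensity, ties broken toward higher index
    order = np.lexsort((np.arange(n), flat))[::-1]
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    parent = np.arange(n, dtype=np.int64)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def ascend(start: int) -> list[int]:
        """Steepest-ascent walk to a local maximum, ties by pixel index."""
        path = [start]
        cur = start
        while True:
            best = None
            for nb in _neighbors(cur, h, w):
                if rank[nb] < rank[cur] and (best is None or rank[nb] < rank[best]):
                    best = nb
            if best is None:
                return path
            path.append(best)
            cur = best

    processed = np.zeros(n, dtype=bool)
    events = []   # (persistence, saddle, path_dying, path_surv)
    for p in order:
        if flat[p] <= params.support_floor:
            break       # order is descending: everything below is off-domain
        nb_roots: dict[int, int] = {}
        for nb in _neighbors(p, h, w):
            if processed[nb]:
                r = find(nb)
                if r not in nb_roots or rank[nb] < rank[nb_roots[r]]:
                    nb_roots[r] = nb    # best (highest) neighbour per component
        processed[p] = True
        if not nb_roots:
            continue    # local maximum: new component rooted at p
        roots = sorted(nb_roots, key=lambda r: rank[r])
        surv = roots[0]
        surv_path = None
        if len(roots) > 1:
            surv_path = ascend(nb_roots[surv])
        for r in roots[1:]:
            dying_path = ascend(nb_roots[r])
            persistence = flat[r] - flat[p]
            events.append((float(persistence), int(p), dying_path, surv_path))
            parent[r] = surv
        parent[p] = surv

    # --- build the raw arc graph: nodes are maxima (ascent terminals) ---
    nodes: dict[int, tuple[float, float]] = {}
    edges: dict[int, dict] = {}
    incident: dict[int, set[int]] = {}
    eid_gen = itertools.count()

    def node_pos(pix: int) -> tuple[float, float]:
        r, c = divmod(pix, w)
        return (float(c), float(r))

    def add_edge_record(u: int, v: int, poly_pix: list[int], persistence: float) -> None:
        eid = next(eid_gen)
        edges[eid] = {"u": u, "v": v, "poly": poly_pix, "pers": persistence}
        for t in (u, v):
            nodes.setdefault(t, node_pos(t))
            incident.setdefault(t, set()).add(eid)

    for persistence, saddle, dying_path, surv_path in events:
        u = dying_path[-1]              # terminal maximum on the dying side
        v = surv_path[-1]
        poly = list(reversed(dying_path)) + [saddle] + surv_path
        add_edge_record(u, v, poly, persistence)

    # --- cancellation: dissolve low-persistence peaks in ascending order ---
    for eid in sorted(edges, key=lambda e: edges[e]["pers"]):
        if eid not in edges:
            continue
        e = edges[eid]
        if e["pers"] >= cutoff:
            break
        u, v = e["u"], e["v"]
        m, other = (u, v) if rank[u] > rank[v] else (v, u)   # cancel the lower peak
        rest = incident[m] - {eid}
        if len(rest) >= 2:
            continue    # junction-supported peak: keep the pair
        # orient e's polyline from m to the other endpoint
        poly_m_other = e["poly"] if e["poly"][0] == m else list(reversed(e["poly"]))
        del edges[eid]
        incident[u].discard(eid)
        incident[v].discard(eid)
        if len(rest) == 1:
            fid = next(iter(rest))
            f = edges[fid]
            fpoly = f["poly"] if f["poly"][-1] == m else list(reversed(f["poly"]))
            f["poly"] = fpoly + poly_m_other[1:]
            fu = f["poly"][0]
            f["u"], f["v"] = fu, other
            incident[m].discard(fid)
            incident.setdefault(other, set()).add(fid)
        if not incident.get(m):
            incident.pop(m, None)
            nodes.pop(m, None)

    out = EmbeddedGraph(pixel_size_um=pixel_size_um)
    used = set()
    for eid, e in edges.items():
        for t in (e["u"], e["v"]):
            if t not in used:
                out.add_vertex(t, *node_pos(t))
                used.add(t)
        poly_xy = np.array([node_pos(pix) for pix in e["poly"]], dtype=float)
        out.add_edge(e["u"], e["v"], poly_xy)
    return out


def prune_and_filter(graph: EmbeddedGraph, params: MorseParams | None = None) -> EmbeddedGraph:
    """Remove short leaf branches (< ``min_branch_um``), iterating to a
    fixed point with degree-2 chains merged between passes; optionally
    keep only the component with the largest total length."""
    params = params or MorseParams()
    g = graph.merge_degree2_chains()
    while True:
        branches = g.branches()
        to_remove = []
        for br in branches:
            u, v = br["nodes"]
            is_leaf = g.graph.degree(u) == 1 or g.graph.degree(v) == 1
            if is_leaf and br["length_um"] < params.min_branch_um:
                to_remove.append(br)
        if not to_remove:
            break
        for br in to_remove:
            for (u, v, k) in br["edges"]:
                if g.graph.has_edge(u, v, k):
                    g.graph.remove_edge(u, v, k)
        g.graph.remove_nodes_from([nd for nd in list(g.graph.nodes) if g.graph.degree(nd) == 0])
        g = g.merge_degree2_chains()

    if params.remove_disconnected and g.graph.number_of_nodes() > 0:
        comps = list(nx.connected_components(g.graph))
        if len(comps) > 1:
            def comp_length(c):
                return sum(d["length_px"] for u, v, d in g.graph.edges(c, data=True))
            best = max(comps, key=comp_length)
            g.graph.remove_nodes_from([nd for nd in list(g.graph.nodes) if nd not in best])
    return g


def smooth_branches(graph: EmbeddedGraph, window: int | None = None) -> EmbeddedGraph:
    """Smooth each branch polyline with a centred moving average.

    Interior points are replaced by the mean of a symmetric window
    (shrunk near the ends so it stays centred); branch endpoints —
    junctions and leaves — are fixed, so topology and connectivity are
    unchanged.  Collinear evenly spaced points are left exactly in
    place.
    """
    if window is None:
        window = 5
    if window < 3 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 3")
    half = window // 2
    out = graph.copy()
    for u, v, k, d in out.graph.edges(keys=True, data=True):
        poly = np.asarray(d["polyline"], dtype=float)
        m = len(poly)
        if m <= 2:
            continue
        sm = poly.copy()
        for i in range(1, m - 1):
            hh = min(half, i, m - 1 - i)
            sm[i] = poly[i - hh : i + hh + 1].mean(axis=0)
        d["polyline"] = sm
        d["length_px"] = _polyline_length(sm)
    return out


def export_graph(graph: EmbeddedGraph, graphml_path=None, csv_path=None) -> None:
    """Write the embedded graph as GraphML and/or a plain CSV edge list.

    The CSV has one row per edge: ``v1, v2, length_um, polyline`` with
    the polyline as semicolon-separated ``x,y`` pixel coordinates.  The
    GraphML carries node positions and edge lengths (polylines are
    serialised to the same string form, since GraphML values are
    scalars).
    """
    if graphml_path is not None:
        g = nx.MultiGraph()
        for n, d in graph.graph.nodes(data=True):
            g.add_node(n, x=float(d["pos"][0]), y=float(d["pos"][1]))
        for u, v, k, d in graph.graph.edges(keys=True, data=True):
            poly = ";".join(f"{x:.2f},{y:.2f}" for x, y in d["polyline"])
            g.add_edge(u, v, key=k, length_um=d["length_px"] * graph.pixel_size_um, polyline=poly)
        nx.write_graphml(g, graphml_path)
    if csv_path is not None:
        with open(csv_path, "w") as fh:
            fh.write("v1,v2,length_um,polyline\n")
            for u, v, k, d in graph.graph.edges(keys=True, data=True):
                poly = ";".join(f"{x:.2f},{y:.2f}" for x, y in d["polyline"])
                fh.write(f"{u},{v},{d['length_px'] * graph.pixel_size_um:.4f},\"{poly}\"\n")


def graph_to_networkx_simple(graph: EmbeddedGraph) -> nx.Graph:
    """Length-weighted simple view used by the topology stage (parallel
    edges keep the shortest; lengths in um)."""
    g = nx.Graph()
    for nd, data in graph.graph.nodes(data=True):
        g.add_node(nd, pos=data["pos"])
    for u, v, d in graph.graph.edges(data=True):
        lum = d["length_px"] * graph.pixel_size_um
        if g.has_edge(u, v):
            if lum < g.edges[u, v]["length_um"]:
                g.edges[u, v]["length_um"] = lum
        elif u != v:
            g.add_edge(u, v, length_um=lum)
    return g
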