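"""Independent brute-force oracles for graph metrics and morphology.

These deliberately avoid the code paths used by the package (networkx
metric routines, scikit-image reconstruction): shortest paths are found
by breadth-first search and exhaustive shortest-path enumeration,
triangles by explicit triple loops, and the Fiedler value through a
different eigensolver route, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# Morphology: 1-D / 2-D reconstruction-by-erosion by fixpoint iteration

def iterative_h_minima(g: np.ndarray, h: float) -> np.ndarray:
    """Reconstruction-by-erosion of g + h over g by naive iteration
    (4-neighbor erosion, repeated to the fixpoint)."""
    g = np.asarray(g, dtype=float)
    out = g + h
    while True:
        padded = np.pad(out, 1, constant_values=np.inf)
        eroded = np.minimum.reduce([
            padded[1:-1, 1:-1], padded[:-2, 1:-1], padded[2:, 1:-1],
            padded[1:-1, :-2], padded[1:-1, 2:],
        ])
        nxt = np.maximum(g, eroded)
        if np.array_equal(nxt, out):
            return out
        out = nxt


# ---------------------------------------------------------------------------
# Graph helpers (adjacency dict of sets; weights dict keyed by (u, v))

def graph_dicts(G):
    adj = {u: set(G.neighbors(u)) for u in G.nodes}
    w = {}
    for u, v, d in G.edges(data=True):
        w[(u, v)] = w[(v, u)] = d["weight"]
    return adj, w


def bfs_dist(adj, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def oracle_strength(G):
    adj, w = graph_dicts(G)
    return {u: sum(w[(u, v)] for v in adj[u]) for u in adj}


def oracle_clustering(G):
    adj, _ = graph_dicts(G)
    out = {}
    for u in adj:
        k = len(adj[u])
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(adj[u], 2)
                    if b in adj[a])
        out[u] = 2.0 * links / (k * (k - 1))
    return out


def oracle_triangles(G):
    adj, _ = graph_dicts(G)
    nodes = sorted(adj)
    tri = 0
    for a, b, c in itertools.combinations(nodes, 3):
        if b in adj[a] and c in adj[a] and c in adj[b]:
            tri += 1
    return tri


def oracle_transitivity(G):
    adj, _ = graph_dicts(G)
    triplets = sum(len(adj[u]) * (len(adj[u]) - 1) / 2 for u in adj)
    if triplets == 0:
        return 0.0
    return 3.0 * oracle_triangles(G) / triplets


def oracle_eccentricity(G, component):
    adj, _ = graph_dicts(G)
    return {u: max(bfs_dist(adj, u)[v] for v in component) for u in component}


def oracle_mean_spl(G):
    adj, _ = graph_dicts(G)
    out = {}
    for u in adj:
        d = bfs_dist(adj, u)
        vals = [v for k, v in d.items() if k != u]
        out[u] = float(np.mean(vals)) if vals else np.nan
    return out


def oracle_efficiency(G):
    adj, _ = graph_dicts(G)
    nodes = list(adj)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for u in nodes:
        d = bfs_dist(adj, u)
        total += sum(1.0 / d[v] for v in nodes if v != u and v in d)
    return total / (n * (n - 1))


def _all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path by DFS over the BFS-distance DAG."""
    dist = bfs_dist(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for v in adj[node]:
            if dist.get(v, -1) == dist[node] + 1 and dist[v] <= dist[t]:
                walk(v, path + [v])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def oracle_betweenness(G):
    """Fraction of shortest paths through each node, normalized as
    2 / ((n-1)(n-2)) over unordered endpoint pairs."""
    adj, _ = graph_dicts(G)
    nodes = sorted(adj)
    n = len(nodes)
    bc = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {u: x * scale for u, x in bc.items()}
    return bc


def oracle_s_metric(G):
    deg = {u: G.degree(u) for u in G.nodes}
    return float(sum(deg[u] * deg[v] for u, v in G.edges))


def oracle_assortativity(G):
    deg = {u: G.degree(u) for u in G.nodes}
    xs, ys = [], []
    for u, v in G.edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def oracle_density(G):
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def oracle_degree_weight_pearson(G):
    adj, w = graph_dicts(G)
    deg, mw = [], []
    for u in adj:
        if not adj[u]:
            continue
        deg.append(len(adj[u]))
        mw.append(np.mean([w[(u, v)] for v in adj[u]]))
    deg, mw = np.asarray(deg, float), np.asarray(mw, float)
    if len(deg) < 2 or deg.std() == 0 or mw.std() == 0:
        return np.nan
    return float(np.corrcoef(deg, mw)[0, 1])


def oracle_algebraic_connectivity(G):
    """Fiedler value through networkx's iterative solver (a different
    route from the package's dense eigendecomposition)."""
    import networkx as nx
    if G.number_of_nodes() < 2:
        return np.nan
    if not nx.is_connected(G):
        return 0.0
    return float(nx.algebraic_connectivity(G, weight=None, method="tracemin_lu"))


def oracle_modularity(G, communities):
    """Newman modularity of a given partition from the definition
    Q = sum_c [ L_c / m - (d_c / 2m)^2 ] (unweighted)."""
    m = G.number_of_edges()
    if m == 0:
        return np.nan
    q = 0.0
    for comm in communities:
        comm = set(comm)
        l_c = sum(1 for u, v in G.edges if u in comm and v in comm)
        d_c = sum(G.degree(u) for u in comm)
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Random planar test graphs

def random_planar_graph(rng, n_min=4, n_max=15):
    """Random Delaunay triangulation graph (planar) with random positive
    edge weights; occasionally thinned, which preserves planarity."""
    import networkx as nx
    from scipy.spatial import Delaunay

    n = int(rng.integers(n_min, n_max + 1))
    pts = rng.uniform(size=(n, 2))
    tri = Delaunay(pts)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex.tolist(), 2):
            G.add_edge(a, b)
    if rng.uniform() < 0.5 and G.number_of_edges() > n:
        drop = rng.choice(G.number_of_edges(),
                          size=int(0.2 * G.number_of_edges()), replace=False)
        edges = list(G.edges)
        G.remove_edges_from([edges[i] for i in drop])
    for u, v in G.edges:
        G.edges[u, v]["weight"] = float(rng.uniform(0.5, 3.0))
    return G
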