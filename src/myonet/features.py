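"""The canonical 82-slot feature catalog and its extractors.

Each analyzed image is summarized by 82 numbers in a fixed order:

* 1-16   geometric: mean/sd of fiber size and shape descriptors plus the
         collagen (A1/A2 fibrosis index) pair;
* 17-24  neighborhood: fiber neighbor counts, overall, per type, and per
         type-of-neighbor;
* 25-38  relation: each geometric quantity divided by its mean over the
         fiber's neighbors (mean/sd over fibers);
* 39-82  graph theory: per-node network metrics summarized over all/slow/
         fast fibers, plus whole-network scalars and type-subgraph
         density/modularity.

Entries that cannot be computed (e.g. fast-fiber statistics on an
all-slow image, or eccentricity on a disconnected network) are flagged
undefined and carried as NaN, never as silent zeros.

Statistical conventions: all standard deviations are population (ddof=0);
the orientation angle, periodic over 180 degrees, uses circular mean/sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from myonet.core import FAST, SLOW

N_FEATURES = 82

#: Per-fiber geometric quantities used by the relation block, in catalog order.
RELATION_QUANTITIES = (
    "area_A2", "major", "minor", "axis_ratio", "convexity", "angle", "a1_over_a2",
)


def catalog() -> pd.DataFrame:
    """The machine-readable feature registry (index 1..82)."""
    rows: list[dict] = []

    def add(idx, name, group, population, statistic):
        rows.append(dict(index=idx, name=name, group=group,
                         population=population, statistic=statistic))

    for i, (qty, grp) in enumerate(
            [("fiber area", "size"), ("major axis", "size"), ("minor axis", "size")]):
        add(2 * i + 1, f"mean {qty}", grp, "all", "mean")
        add(2 * i + 2, f"sd {qty}", grp, "all", "sd")
    for i, qty in enumerate(["axis ratio", "convexity", "orientation angle",
                             "eccentricity"]):
        add(7 + 2 * i, f"mean {qty}", "shape", "all", "mean")
        add(8 + 2 * i, f"sd {qty}", "shape", "all", "sd")
    add(15, "mean A1/A2 (fibrosis index)", "collagen", "all", "mean")
    add(16, "sd A1/A2 (fibrosis index)", "collagen", "all", "sd")

    add(17, "mean neighbor count", "neighborhood", "all", "mean")
    add(18, "sd neighbor count", "neighborhood", "all", "sd")
    add(19, "mean neighbor count of slow fibers", "neighborhood", "slow", "mean")
    add(20, "mean neighbor count of fast fibers", "neighborhood", "fast", "mean")
    for i, (pop, kind) in enumerate(
            [("slow", "slow"), ("slow", "fast"), ("fast", "slow"), ("fast", "fast")]):
        add(21 + i, f"mean {kind} neighbors of {pop} fibers",
            "neighborhood", pop, "mean")

    rel_names = ["area", "major axis", "minor axis", "axis ratio", "convexity",
                 "orientation angle", "A1/A2"]
    for i, qty in enumerate(rel_names):
        add(25 + 2 * i, f"mean relation {qty}", "relation", "all", "mean")
        add(26 + 2 * i, f"sd relation {qty}", "relation", "all", "sd")

    metrics = ["strength", "clustering coefficient", "eccentricity",
               "betweenness centrality", "mean shortest-path length"]
    idx = 39
    for m in metrics:
        for stat in ("mean", "sd"):
            for pop in ("all", "slow", "fast"):
                add(idx, f"{stat} {m} ({pop})", "graph", pop, stat)
                idx += 1
    scalars = ["radius", "diameter", "global efficiency",
               "degree-weight Pearson correlation", "algebraic connectivity",
               "s-metric", "degree assortativity", "density", "transitivity",
               "modularity"]
    for m in scalars:
        add(idx, m, "graph", "all", "scalar")
        idx += 1
    for pop in ("slow", "fast"):
        for m in ("density", "modularity"):
            add(idx, f"{m} of {pop}-only subgraph", "graph", pop, "scalar")
            idx += 1
    df = pd.DataFrame(rows).set_index("index").sort_index()
    assert len(df) == N_FEATURES
    return df


@dataclass
class FeatureVector:
    """82 real values keyed by catalog index, with undefined-entry flags."""

    image_id: str
    values: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")
        if self.defined is None:
            self.defined = ~np.isnan(self.values)
        self.defined = np.asarray(self.defined, dtype=bool)

    def __getitem__(self, index: int) -> float:
        """Value for a 1-based catalog index."""
        return float(self.values[index - 1])

    def is_defined(self, index: int) -> bool:
        return bool(self.defined[index - 1])

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, index=[f"f{i:02d}" for i in range(1, 83)])
        s.name = self.image_id
        return s


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return np.nan, np.nan
    return float(v.mean()), float(v.std(ddof=0))


def _circular_mean_sd_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean/sd of axial data with a 180-degree period, in degrees."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float)) * 2.0
    a = a[~np.isnan(a)]
    if len(a) == 0:
        return np.nan, np.nan
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(c, s))
    mean = np.rad2deg(np.arctan2(s, c)) / 2.0
    sd = np.rad2deg(np.sqrt(max(-2.0 * np.log(max(r, 1e-300)), 0.0))) / 2.0
    return float(mean), float(sd)


def _interior(g: nx.Graph) -> list:
    """Nodes entering per-image statistics: fibers not truncated by the
    ROI border (border fibers stay in the graph as padding)."""
    nodes = [n for n, d in g.nodes(data=True) if not d.get("border_flag", False)]
    return nodes if nodes else list(g.nodes)


def geometric_block(fibers: pd.DataFrame, a1: dict[int, int]) -> dict[int, float]:
    """Features 1-16 from the interior fibers of the table."""
    df = fibers[~fibers["border_flag"]]
    if len(df) < 3:
        raise ValueError("fewer than 3 interior fibers")
    missing = [i for i in df["id"] if int(i) not in a1]
    if missing:
        raise ValueError(f"network stage not run: fibers {missing} missing A1")
    out: dict[int, float] = {}
    out[1], out[2] = _mean_sd(df["area_A2"].to_numpy(float))
    out[3], out[4] = _mean_sd(df["major"].to_numpy(float))
    out[5], out[6] = _mean_sd(df["minor"].to_numpy(float))
    minor = df["minor"].to_numpy(float)
    ratio = np.where(minor > 0, df["major"].to_numpy(float) / np.maximum(minor, 1e-12),
                     np.nan)
    out[7], out[8] = _mean_sd(ratio)
    out[9], out[10] = _mean_sd(df["convexity"].to_numpy(float))
    out[11], out[12] = _circular_mean_sd_deg(df["angle"].to_numpy(float))
    out[13], out[14] = _mean_sd(df["eccentricity"].to_numpy(float))
    fib_index = np.array([a1[int(i)] / a for i, a in
                          zip(df["id"], df["area_A2"].to_numpy(float))])
    out[15], out[16] = _mean_sd(fib_index)
    return out


def neighborhood_block(net: nx.Graph) -> dict[int, float]:
    """Features 17-24: neighbor counts overall, per type, per neighbor type."""
    interior = _interior(net)
    deg = dict(net.degree())
    out: dict[int, float] = {}
    out[17], out[18] = _mean_sd(np.array([deg[n] for n in interior], float))

    by_type = {SLOW: [n for n in interior if net.nodes[n]["type"] == SLOW],
               FAST: [n for n in interior if net.nodes[n]["type"] == FAST]}
    out[19] = _mean_sd(np.array([deg[n] for n in by_type[SLOW]], float))[0]
    out[20] = _mean_sd(np.array([deg[n] for n in by_type[FAST]], float))[0]

    def same_kind_counts(pop: str, kind: str) -> float:
        vals = []
        for n in by_type[pop]:
            vals.append(sum(1 for m in net.neighbors(n)
                            if net.nodes[m]["type"] == kind))
        return _mean_sd(np.array(vals, float))[0]

    out[21] = same_kind_counts(SLOW, SLOW)
    out[22] = same_kind_counts(SLOW, FAST)
    out[23] = same_kind_counts(FAST, SLOW)
    out[24] = same_kind_counts(FAST, FAST)
    return out


def relation_block(net: nx.Graph) -> dict[int, float]:
    """Features 25-38: per-fiber quantity relative to its neighbors' mean.

    Isolated fibers, and fibers whose neighbor mean is (numerically) zero,
    are excluded from the statistics.
    """
    interior = _interior(net)
    out: dict[int, float] = {}
    for qi, qty in enumerate(RELATION_QUANTITIES):
        rels = []
        for n in interior:
            nbrs = list(net.neighbors(n))
            if not nbrs:
                continue
            v = net.nodes[n].get(qty, np.nan)
            nv = np.array([net.nodes[m].get(qty, np.nan) for m in nbrs], float)
            nv = nv[~np.isnan(nv)]
            if len(nv) == 0 or np.isnan(v):
                continue
            denom = nv.mean()
            if abs(denom) < 1e-9:
                continue
            rels.append(v / denom)
        out[25 + 2 * qi], out[26 + 2 * qi] = _mean_sd(np.array(rels, float))
    return out


# ---------------------------------------------------------------------------
# Graph-theory block

def _modularity(g: nx.Graph) -> float:
    """Greedy agglomerative modularity (unweighted, deterministic)."""
    if g.number_of_edges() == 0:
        return np.nan
    comms = nx.algorithms.community.greedy_modularity_communities(g, weight=None)
    return float(nx.algorithms.community.modularity(g, comms, weight=None))


def degree_weight_pearson(g: nx.Graph) -> float:
    """Pearson correlation between node degree and mean incident edge weight."""
    deg, mw = [], []
    for n in g.nodes:
        d = g.degree(n)
        if d == 0:
            continue
        deg.append(d)
        mw.append(np.mean([g.edges[n, m]["weight"] for m in g.neighbors(n)]))
    if len(deg) < 2:
        return np.nan
    deg = np.asarray(deg, float)
    mw = np.asarray(mw, float)
    if deg.std() == 0 or np.std(mw) == 0:
        return np.nan
    return float(np.corrcoef(deg, mw)[0, 1])


def s_metric(g: nx.Graph) -> float:
    """Sum over edges of the product of endpoint degrees."""
    deg = dict(g.degree())
    return float(sum(deg[u] * deg[v] for u, v in g.edges))


def algebraic_connectivity(g: nx.Graph) -> float:
    """Second-smallest eigenvalue of the unweighted Laplacian (dense solve)."""
    n = g.number_of_nodes()
    if n < 2:
        return np.nan
    lap = nx.laplacian_matrix(g, weight=None).toarray().astype(float)
    eig = np.linalg.eigvalsh(lap)
    return float(eig[1])


def graph_block(net: nx.Graph) -> dict[int, float]:
    """Features 39-82: node-metric summaries and whole-network scalars.

    Shortest-path-based quantities are unweighted; strength sums edge
    weights. On a disconnected network, eccentricity/radius/diameter are
    computed on the largest component and per-node path lengths average
    over reachable nodes only; global efficiency counts unreachable pairs
    as zero.
    """
    out: dict[int, float] = {i: np.nan for i in range(39, 83)}
    n = net.number_of_nodes()
    if n < 3:
        return out

    interior = _interior(net)
    pops = {
        "all": interior,
        "slow": [x for x in interior if net.nodes[x]["type"] == SLOW],
        "fast": [x for x in interior if net.nodes[x]["type"] == FAST],
    }

    strength = {x: sum(net.edges[x, m]["weight"] for m in net.neighbors(x))
                for x in net.nodes}
    clustering = nx.clustering(net)
    betweenness = nx.betweenness_centrality(net, normalized=True, weight=None)

    spl = dict(nx.all_pairs_shortest_path_length(net))
    components = list(nx.connected_components(net))
    largest = max(components, key=lambda c: (len(c), sorted(c)[0]))
    ecc = {x: max(spl[x].values()) for x in largest} if len(largest) > 1 else {}
    mean_spl = {}
    for x in net.nodes:
        d = [v for k, v in spl[x].items() if k != x]
        mean_spl[x] = float(np.mean(d)) if d else np.nan

    node_metrics = [strength, clustering, ecc, betweenness, mean_spl]
    idx = 39
    for metric in node_metrics:
        stats = {}
        for pop_name, members in pops.items():
            vals = np.array([metric.get(x, np.nan) for x in members], float)
            stats[pop_name] = _mean_sd(vals)
        for si, stat in enumerate((0, 1)):
            for pop_name in ("all", "slow", "fast"):
                out[idx] = stats[pop_name][stat]
                idx += 1

    if len(largest) > 1:
        out[69] = float(min(ecc[x] for x in largest))
        out[70] = float(max(ecc[x] for x in largest))
    out[71] = float(nx.global_efficiency(net))
    out[72] = degree_weight_pearson(net)
    out[73] = algebraic_connectivity(net)
    out[74] = s_metric(net)
    try:
        assort = float(nx.degree_assortativity_coefficient(net))
        out[75] = assort if np.isfinite(assort) else np.nan
    except (ZeroDivisionError, ValueError):
        out[75] = np.nan
    out[76] = float(nx.density(net))
    out[77] = float(nx.transitivity(net))
    out[78] = _modularity(net)

    idx = 79
    for pop in (SLOW, FAST):
        sub = net.subgraph([x for x, d in net.nodes(data=True)
                            if d["type"] == pop])
        out[idx] = float(nx.density(sub)) if sub.number_of_nodes() >= 2 else np.nan
        out[idx + 1] = _modularity(sub) if sub.number_of_edges() > 0 else np.nan
        idx += 2
    return out


def feature_vector(fibers: pd.DataFrame, net: nx.Graph, a1: dict[int, int],
                   image_id: str = "") -> FeatureVector:
    """Concatenate the four blocks into the canonical 82-entry vector."""
    values = np.full(N_FEATURES, np.nan)
    for block in (geometric_block(fibers, a1), neighborhood_block(net),
                  relation_block(net), graph_block(net)):
        for idx, v in block.items():
            values[idx - 1] = v
    return FeatureVector(image_id=image_id, values=values)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per image: f01..f82 plus und01..und82 undefined flags."""
    rows = []
    for fv in vectors:
        row = {"image_id": fv.image_id}
        for i in range(1, N_FEATURES + 1):
            row[f"f{i:02d}"] = fv.values[i - 1]
        for i in range(1, N_FEATURES + 1):
            row[f"und{i:02d}"] = not fv.defined[i - 1]
        rows.append(row)
    return pd.DataFrame(rows)
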