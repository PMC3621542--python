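"""Fiber adjacency network from the expansion mosaic.

Each segmented fiber is expanded outward until it meets its neighbors,
assigning every collagen pixel to the nearest fiber. The resulting mosaic
defines fiber adjacency (shared mosaic borders) and the expanded area A1
of each fiber; A1/A2 is the per-fiber fibrosis index. The network has one
node per fiber and an edge between adjacent fibers, weighted by the
centroid-to-centroid distance in pixels.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from myonet.core import LabelMap

#: Node attributes copied from the fiber table onto the network.
NODE_ATTRS = ("type", "x", "y", "area_A2", "major", "minor", "angle",
              "convexity", "eccentricity", "border_flag")


def expand_fibers(labels: LabelMap) -> tuple[np.ndarray, dict[int, int]]:
    """Assign every boundary/collagen pixel to its nearest fiber.

    Returns the full mosaic partition (no zero pixels) and the expanded
    area A1 of each fiber, the area of its mosaic cell including the
    original fiber, so A1 >= A2 always.
    """
    lab = labels.labels
    if lab.max(initial=0) == 0:
        raise ValueError("empty label map")
    _, (ri, ci) = ndi.distance_transform_edt(lab == 0, return_indices=True)
    mosaic = lab[ri, ci]
    counts = np.bincount(mosaic.ravel())
    a1 = {k: int(counts[k]) for k in range(1, len(counts)) if counts[k] > 0}
    return mosaic, a1


def mosaic_contacts(mosaic: np.ndarray) -> dict[tuple[int, int], int]:
    """Contact length (in 4-neighbor pixel pairs) between mosaic cells."""
    contacts: dict[tuple[int, int], int] = {}
    for a, b in ((mosaic[:, :-1], mosaic[:, 1:]), (mosaic[:-1, :], mosaic[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs, counts = np.unique(np.column_stack([lo, hi]), axis=0,
                                  return_counts=True)
        for (i, j), c in zip(pairs, counts):
            key = (int(i), int(j))
            contacts[key] = contacts.get(key, 0) + int(c)
    return contacts


def build_network(mosaic: np.ndarray, fibers: pd.DataFrame,
                  a1: dict[int, int] | None = None,
                  min_contact_px: int = 1) -> nx.Graph:
    """Weighted undirected fiber network.

    Nodes are fiber ids with geometric attributes (plus A1/A2 when the
    expansion areas are supplied); edges join fibers whose mosaic cells
    share a border of at least ``min_contact_px`` pixel contacts, weighted
    by the Euclidean centroid distance. A disconnected result is allowed
    and flagged in ``G.graph['connected']``.
    """
    g = nx.Graph()
    fib = fibers.set_index("id")
    for fid, row in fib.iterrows():
        attrs = {k: row[k] for k in NODE_ATTRS}
        minor = row["minor"]
        attrs["axis_ratio"] = float(row["major"] / minor) if minor > 0 else np.nan
        if a1 is not None:
            attrs["A1"] = a1.get(int(fid), np.nan)
            attrs["a1_over_a2"] = (a1[int(fid)] / row["area_A2"]
                                   if int(fid) in a1 else np.nan)
        g.add_node(int(fid), **attrs)

    for (i, j), c in mosaic_contacts(mosaic).items():
        if c < min_contact_px:
            continue
        if i not in g or j not in g:
            continue
        dx = fib.at[i, "x"] - fib.at[j, "x"]
        dy = fib.at[i, "y"] - fib.at[j, "y"]
        w = float(np.hypot(dx, dy))
        if w <= 0:
            continue
        g.add_edge(i, j, weight=w)
    g.graph["connected"] = nx.is_connected(g) if g.number_of_nodes() > 0 else False
    return g


def write_network(g: nx.Graph, edge_path, node_path) -> None:
    """Serialize the network as edge-list and node-attribute CSVs."""
    edges = pd.DataFrame(
        [(i, j, d["weight"]) for i, j, d in g.edges(data=True)],
        columns=["i", "j", "weight"],
    )
    edges.to_csv(edge_path, index=False)
    nodes = pd.DataFrame([{"id": n, **d} for n, d in g.nodes(data=True)])
    nodes.to_csv(node_path, index=False)
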