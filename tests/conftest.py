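"""Shared fixtures: analyzed synthetic images are expensive, so the ones
used by several test modules are computed once per session."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from myonet.pipeline import analyze_image
from myonet.synthetic import SyntheticSpec, generate_biopsy

NODE_DEFAULTS = dict(type="slow", x=0.0, y=0.0, area_A2=100.0, major=12.0,
                     minor=10.0, angle=10.0, convexity=1.0, eccentricity=0.5,
                     axis_ratio=1.2, a1_over_a2=1.1, border_flag=False)


def make_graph(nodes: dict, edges: list) -> nx.Graph:
    """Toy fiber network: ``nodes`` maps id -> attribute overrides,
    ``edges`` is a list of (i, j) or (i, j, weight)."""
    g = nx.Graph()
    for nid, overrides in nodes.items():
        attrs = dict(NODE_DEFAULTS)
        attrs.update(overrides)
        g.add_node(nid, **attrs)
    for e in edges:
        if len(e) == 2:
            i, j = e
            w = 1.0
        else:
            i, j, w = e
        g.add_edge(i, j, weight=w)
    return g


@pytest.fixture(scope="session")
def default_biopsy():
    """One default synthetic biopsy (49 fibers, mild fibrosis) + truth."""
    return generate_biopsy(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def default_result(default_biopsy):
    img, _ = default_biopsy
    return analyze_image(img.rgb, image_id="default")
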