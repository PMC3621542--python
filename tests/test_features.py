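"""Feature catalog layout, block formulas, and graph-metric oracle checks."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from conftest import make_graph
from myonet.features import (
    FeatureVector,
    N_FEATURES,
    catalog,
    feature_vector,
    geometric_block,
    graph_block,
    neighborhood_block,
    relation_block,
)


class TestCatalog:
    def test_group_sizes(self):
        cat = catalog()
        sizes = cat["group"].value_counts().to_dict()
        assert sizes == {"size": 6, "shape": 8, "collagen": 2,
                         "neighborhood": 8, "relation": 14, "graph": 44}
        assert list(cat.index) == list(range(1, 83))

    def test_anchored_entries(self):
        cat = catalog()
        assert "A1/A2" in cat.loc[15, "name"]
        assert cat.loc[17, "name"] == "mean neighbor count"
        assert cat.loc[18, "statistic"] == "sd"
        assert "major axis" in cat.loc[27, "name"] and "relation" in cat.loc[27, "name"]
        assert cat.loc[41, "name"] == "mean strength (fast)"


def _square_fibers(n=4, area=100.0):
    rows = []
    for i in range(n):
        rows.append(dict(id=i + 1, x=10.0 * i, y=0.0, area_A2=area,
                         major=12.0, minor=12.0, angle=15.0, convexity=1.0,
                         eccentricity=0.0, type="slow", border_flag=False,
                         mean_red=200.0))
    return pd.DataFrame(rows)


class TestGeometricBlock:
    def test_identical_fibers_have_zero_sds(self):
        df = _square_fibers()
        a1 = {i: 110 for i in df["id"]}
        vals = geometric_block(df, a1)
        for idx in (2, 4, 6, 8, 10, 12, 14, 16):
            assert vals[idx] == pytest.approx(0.0, abs=1e-9)
        assert vals[1] == pytest.approx(df["area_A2"].mean())
        assert vals[15] == pytest.approx(1.1)

    def test_missing_a1_is_an_error(self):
        df = _square_fibers()
        with pytest.raises(ValueError, match="network stage"):
            geometric_block(df, {1: 110})

    def test_angular_sd_is_circular(self):
        # angles at +/-80 degrees are 20 degrees apart on the 180-degree
        # circle, not 160
        df = _square_fibers()
        df["angle"] = [80.0, -80.0, 80.0, -80.0]
        a1 = {i: 110 for i in df["id"]}
        vals = geometric_block(df, a1)
        assert vals[12] < 30.0


class TestNeighborhoodBlock:
    def test_path_graph_hand_computation(self):
        g = make_graph({1: {}, 2: {}, 3: {}}, [(1, 2), (2, 3)])
        vals = neighborhood_block(g)
        assert vals[17] == pytest.approx(4 / 3)
        assert vals[18] == pytest.approx(np.std([1, 2, 1]))

    def test_single_type_image_flags_other_type(self):
        g = make_graph({1: {}, 2: {}, 3: {}}, [(1, 2), (2, 3)])  # all slow
        vals = neighborhood_block(g)
        for idx in (20, 23, 24):
            assert np.isnan(vals[idx])
        assert vals[19] == pytest.approx(4 / 3)
        assert vals[21] == pytest.approx(4 / 3)  # all neighbors are slow

    def test_mixed_types(self):
        g = make_graph({1: {}, 2: {"type": "fast"}, 3: {}}, [(1, 2), (2, 3)])
        vals = neighborhood_block(g)
        assert vals[22] == pytest.approx(1.0)   # slow fibers see 1 fast each
        assert vals[23] == pytest.approx(2.0)   # the fast fiber sees 2 slow
        assert vals[24] == pytest.approx(0.0)   # fast present, no fast pairs


class TestRelationBlock:
    def test_homogeneous_mosaic_relations_are_one(self):
        g = make_graph({i: {} for i in range(1, 5)},
                       [(1, 2), (2, 3), (3, 4), (4, 1)])
        vals = relation_block(g)
        for idx in (25, 27, 29, 31, 33, 37):
            assert vals[idx] == pytest.approx(1.0)
            assert vals[idx + 1] == pytest.approx(0.0, abs=1e-12)

    def test_star_major_axis_relation(self):
        nodes = {1: {"major": 10.0}, 2: {"major": 5.0}, 3: {"major": 5.0},
                 4: {"major": 5.0}}
        g = make_graph(nodes, [(1, 2), (1, 3), (1, 4)])
        vals = relation_block(g)
        assert vals[27] == pytest.approx((2.0 + 3 * 0.5) / 4)

    def test_giant_fiber_relation_above_one(self):
        # giant's relation = 1000/100 = 10; each equal neighbor's is
        # 100/mean(1000, 100) < 1; mean = (10 + 2 * 100/550) / 3
        nodes = {1: {"area_A2": 1000.0}, 2: {"area_A2": 100.0},
                 3: {"area_A2": 100.0}}
        g = make_graph(nodes, [(1, 2), (1, 3), (2, 3)])
        vals = relation_block(g)
        expect = (10.0 + 2 * (100.0 / 550.0)) / 3
        assert vals[25] == pytest.approx(expect)

    def test_isolated_node_excluded(self):
        g = make_graph({1: {}, 2: {}, 3: {}}, [(1, 2)])
        vals = relation_block(g)
        assert vals[25] == pytest.approx(1.0)


class TestGraphBlock:
    def test_triangle_closed_forms(self):
        g = make_graph({1: {}, 2: {}, 3: {}}, [(1, 2), (2, 3), (1, 3)])
        vals = graph_block(g)
        assert vals[45] == pytest.approx(1.0)   # mean clustering
        assert vals[76] == pytest.approx(1.0)   # density
        assert vals[77] == pytest.approx(1.0)   # transitivity

    def test_path_closed_forms(self):
        g = make_graph({1: {}, 2: {}, 3: {}}, [(1, 2), (2, 3)])
        vals = graph_block(g)
        assert vals[71] == pytest.approx((1 + 1 + 0.5) / 3)  # efficiency
        assert vals[73] == pytest.approx(1.0)                # Fiedler value
        assert vals[74] == pytest.approx(4.0)                # s-metric
        assert vals[77] == pytest.approx(0.0)                # transitivity
        assert vals[69] == 1.0 and vals[70] == 2.0           # radius, diameter

    def test_too_small_graph_is_undefined(self):
        g = make_graph({1: {}, 2: {}}, [(1, 2)])
        vals = graph_block(g)
        assert all(np.isnan(v) for v in vals.values())

    def test_metrics_match_bruteforce_oracles_on_random_planar_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            g = orc.random_planar_graph(rng)
            _assert_oracle_agreement(g)


def _assert_oracle_agreement(g, tol=1e-9):
    """Package metrics vs independent brute-force values on one graph."""
    from myonet.features import (algebraic_connectivity, degree_weight_pearson,
                                 s_metric, _modularity)

    for n in g.nodes:
        g.nodes[n].setdefault("type", "slow" if n % 2 else "fast")
        g.nodes[n].setdefault("border_flag", False)
    vals = graph_block(g)
    if g.number_of_nodes() < 3:
        return
    interior = list(g.nodes)

    def ms(d):
        arr = np.array([d.get(x, np.nan) for x in interior], float)
        arr = arr[~np.isnan(arr)]
        return (np.nan, np.nan) if len(arr) == 0 else (arr.mean(), arr.std())

    comps = [set(c) for c in nx.connected_components(g)]
    largest = max(comps, key=len)

    checks = {
        39: ms(orc.oracle_strength(g))[0],
        42: ms(orc.oracle_strength(g))[1],
        45: ms(orc.oracle_clustering(g))[0],
        51: ms(orc.oracle_eccentricity(g, largest))[0]
            if len(largest) > 1 else np.nan,
        57: ms(orc.oracle_betweenness(g))[0],
        63: ms(orc.oracle_mean_spl(g))[0],
        69: min(orc.oracle_eccentricity(g, largest).values())
            if len(largest) > 1 else np.nan,
        70: max(orc.oracle_eccentricity(g, largest).values())
            if len(largest) > 1 else np.nan,
        71: orc.oracle_efficiency(g),
        72: orc.oracle_degree_weight_pearson(g),
        73: orc.oracle_algebraic_connectivity(g),
        74: orc.oracle_s_metric(g),
        75: orc.oracle_assortativity(g),
        76: orc.oracle_density(g),
        77: orc.oracle_transitivity(g),
    }
    for idx, expect in checks.items():
        got = vals[idx]
        if np.isnan(expect):
            assert np.isnan(got), f"feature {idx}: got {got}, expected nan"
        else:
            assert got == pytest.approx(expect, abs=tol), f"feature {idx}"

    # modularity: the greedy partition's Q must equal the formula value
    comms = nx.algorithms.community.greedy_modularity_communities(g, weight=None)
    assert vals[78] == pytest.approx(orc.oracle_modularity(g, comms), abs=tol)


class TestFeatureVector:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector("x", np.zeros(81))

    def test_full_pipeline_vector(self, default_result):
        fv = default_result.features
        assert fv.values.shape == (N_FEATURES,)
        assert int((~fv.defined).sum()) == 0  # two types, connected network

    def test_identical_image_identical_vector(self, default_biopsy):
        from myonet.pipeline import analyze_image
        img, _ = default_biopsy
        v1 = analyze_image(img.rgb).features.values
        v2 = analyze_image(img.rgb).features.values
        assert np.array_equal(v1, v2)

    def test_bounded_features_in_range(self, default_result):
        fv = default_result.features
        for idx in (9, 45, 76, 77):   # convexity/clustering/density/transitivity
            assert 0.0 <= fv[idx] <= 1.0
        assert -0.5 <= fv[78] <= 1.0  # modularity


def test_dimensionless_features_invariant_under_rescaling():
    nodes = {1: {"major": 10.0, "minor": 5.0, "area_A2": 120.0},
             2: {"major": 8.0, "minor": 6.0, "area_A2": 150.0},
             3: {"major": 12.0, "minor": 7.0, "area_A2": 210.0},
             4: {"major": 9.0, "minor": 4.0, "area_A2": 90.0}}
    edges = [(1, 2), (2, 3), (3, 4), (4, 1)]
    for v in nodes.values():
        v["axis_ratio"] = v["major"] / v["minor"]
    g1 = make_graph(nodes, edges)
    s = 2.5
    scaled = {k: dict(v) for k, v in nodes.items()}
    for v in scaled.values():
        v["major"] *= s
        v["minor"] *= s
        v["area_A2"] *= s * s
        v["axis_ratio"] = v["major"] / v["minor"]
    g2 = make_graph(scaled, edges)
    r1, r2 = relation_block(g1), relation_block(g2)
    for idx in r1:
        if np.isnan(r1[idx]):
            assert np.isnan(r2[idx])
        else:
            assert r1[idx] == pytest.approx(r2[idx])
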