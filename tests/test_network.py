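"""Interactome compilation, centralities (vs brute force) and MCODE."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import tcellomics as tc
from tcellomics.network import CentralityProfile


def _edges(rows):
    return pd.DataFrame(rows, columns=["nodeA", "nodeB", "direction"])


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_betweenness(g):
    """Betweenness by explicit shortest-path enumeration."""
    bt = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            bt[v] += frac
    return bt


def brute_centroid(g):
    """Centroid from exhaustive gamma counts over all node pairs."""
    dist = dict(nx.all_pairs_shortest_path_length(g))
    out = {}
    for v in g.nodes:
        best = None
        for w in g.nodes:
            if w == v:
                continue
            gamma_vw = gamma_wv = 0
            for u in g.nodes:
                if u in (v, w):
                    continue
                dv, dw = dist[v].get(u), dist[w].get(u)
                if dv is None or dw is None:
                    continue
                if dv < dw:
                    gamma_vw += 1
                elif dw < dv:
                    gamma_wv += 1
            val = gamma_vw - gamma_wv
            best = val if best is None else min(best, val)
        out[v] = float(best if best is not None else 0)
    return out


def brute_bridging(g):
    bt = brute_betweenness(g)
    out = {}
    for v in g.nodes:
        deg = g.degree(v)
        if deg == 0:
            out[v] = 0.0
            continue
        denom = sum(1.0 / g.degree(u) for u in g.neighbors(v))
        out[v] = bt[v] * (1.0 / deg) / denom if denom > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

class TestCompile:
    def test_dedupe_and_self_loop_removal(self):
        g = tc.compile_interactome([_edges([("a", "b", "none"),
                                            ("b", "a", "none"),
                                            ("a", "a", "none")])])
        assert sorted(g.edges) == [("a", "b")]

    def test_union_of_two_sources(self):
        e1 = _edges([(f"a{i}", f"b{i}", "none") for i in range(100)])
        e2 = _edges([(f"a{i}", f"b{i}", "none") for i in range(50)]
                    + [(f"c{i}", f"d{i}", "none") for i in range(50)])
        g = tc.compile_interactome([e1, e2])
        assert g.number_of_edges() == 150

    def test_id_map_collapses_synonyms_before_dedup(self):
        edges = _edges([("syn1", "c", "none"), ("syn2", "c", "none")])
        g = tc.compile_interactome([edges], id_map={"syn1": "sym",
                                                    "syn2": "sym"})
        assert sorted(g.edges) == [("c", "sym")]

    def test_unmapped_without_passthrough_rejected(self):
        with pytest.raises(ValueError, match="unmapped"):
            tc.compile_interactome([_edges([("a", "b", "none")])],
                                   id_map={"a": "A"}, allow_unmapped=False)

    def test_direction_annotations_preserved_and_merged(self):
        g = tc.compile_interactome([_edges([("a", "b", "AB")]),
                                    _edges([("b", "a", "AB")])])
        assert g.edges["a", "b"]["direction"] == "both"


class TestFirstNeighbors:
    def test_star_center_probe_returns_whole_star(self):
        g = nx.star_graph(5)
        fn = tc.first_neighbors(g, {0})
        assert set(fn.nodes) == set(g.nodes)

    def test_path_leaf_probe(self):
        g = nx.path_graph(["a", "b", "c"])
        fn = tc.first_neighbors(g, {"a"})
        assert set(fn.nodes) == {"a", "b"}
        assert sorted(fn.edges) == [("a", "b")]

    def test_induced_subgraph_equals_adjacency_union(self, interactome_data):
        g, probe, _ = interactome_data
        fn = tc.first_neighbors(g, probe)
        nodes = set(probe)
        for v in probe:
            nodes |= set(g.adj[v])
        assert set(fn.nodes) == nodes
        expected = {tuple(sorted((u, v))) for u, v in g.edges
                    if u in nodes and v in nodes}
        assert {tuple(sorted(e)) for e in fn.edges} == expected

    def test_probe_disjoint_from_graph_rejected(self):
        with pytest.raises(ValueError, match="no probe member"):
            tc.first_neighbors(nx.path_graph(3), {"zz"})


class TestCentralities:
    def test_path_graph_known_values(self):
        g = nx.path_graph(["a", "b", "c"])
        prof = tc.compute_centralities(g).table
        assert prof.loc["b", "betweenness"] == 1.0
        assert prof.loc["a", "betweenness"] == 0.0
        assert list(prof["degree"]) == [1, 2, 1]

    def test_star_centroid_matches_hand_computation(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        prof = tc.compute_centralities(g).table
        assert prof.loc[0, "centroid"] == 3.0
        assert all(prof.loc[leaf, "centroid"] == -3.0 for leaf in [1, 2, 3, 4])
        oracle = brute_centroid(g)
        for v in g.nodes:
            assert prof.loc[v, "centroid"] == oracle[v]

    def test_all_indexes_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(40)
        for rep in range(10):
            g = nx.gnp_random_graph(rng.integers(8, 25), 0.25,
                                    seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            prof = tc.compute_centralities(g).table
            bt, cd, br = (brute_betweenness(g), brute_centroid(g),
                          brute_bridging(g))
            for v in g.nodes:
                assert prof.loc[v, "degree"] == g.degree(v)
                assert prof.loc[v, "betweenness"] == pytest.approx(bt[v])
                assert prof.loc[v, "centroid"] == pytest.approx(cd[v])
                assert prof.loc[v, "bridging"] == pytest.approx(br[v])

    def test_heat_diffusion_limits(self):
        g = nx.path_graph(5)
        seeds = {0}
        near = tc.heat_diffusion(g, seeds, t=1e-6)
        assert near[0] == pytest.approx(1.0, abs=1e-4)
        assert sum(near.values()) == pytest.approx(1.0, abs=1e-9)
        far = tc.heat_diffusion(g, seeds, t=1e3)
        for v in g.nodes:
            assert far[v] == pytest.approx(1 / 5, abs=1e-6)

    def test_isolated_node_flagged_zero_bridging(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("iso")
        prof = tc.compute_centralities(g)
        assert prof.table.loc["iso", "bridging"] == 0.0
        assert "iso" in prof.isolated


class TestThreshold:
    def test_cycle_survives_any_fraction(self):
        g = nx.cycle_graph(6)
        for u, v in g.edges:
            g.edges[u, v]["direction"] = "none"
        prof = tc.compute_centralities(g)
        sub, directed = tc.threshold_directed_subnetwork(g, prof, fraction=1.0)
        assert set(sub.nodes) == set(g.nodes)
        assert directed.number_of_edges() == 0

    def test_mode_all_matches_per_index_brute_filter(self, interactome_data):
        g, probe, _ = interactome_data
        fn = tc.first_neighbors(g, probe)
        prof = tc.compute_centralities(fn, heat_seeds=probe)
        sub, _ = tc.threshold_directed_subnetwork(fn, prof, fraction=0.5,
                                                  mode="all")
        tab = prof.table
        from tcellomics.network import DEFAULT_THRESHOLD_INDEXES
        expected = {v for v in fn.nodes
                    if all(tab.loc[v, i] >= 0.5 * tab[i].mean()
                           for i in DEFAULT_THRESHOLD_INDEXES)}
        assert set(sub.nodes) == expected
        any_sub, _ = tc.threshold_directed_subnetwork(fn, prof, fraction=0.5,
                                                      mode="any")
        assert expected <= set(any_sub.nodes)

    def test_directed_extraction_respects_annotations(self):
        g = nx.Graph()
        g.add_edge("a", "b", direction="AB")
        g.add_edge("b", "c", direction="both")
        g.add_edge("c", "d", direction="none")
        prof = tc.compute_centralities(g)
        _, directed = tc.threshold_directed_subnetwork(
            g, prof, fraction=0.0001, mode="any")
        assert ("a", "b") in directed.edges
        assert ("b", "c") in directed.edges and ("c", "b") in directed.edges
        assert ("c", "d") not in directed.edges

    def test_empty_survivors_is_an_error(self):
        # two nodes, each topping one index and failing the other: under
        # mode=all at fraction 1 nobody survives
        g = nx.Graph()
        g.add_edge("a", "b")
        tab = pd.DataFrame(
            {"degree": [10.0, 1.0], "betweenness": [1.0, 10.0],
             "centroid": [1.0, 1.0], "bridging": [1.0, 1.0],
             "heat": [1.0, 1.0]},
            index=["a", "b"])
        prof = CentralityProfile(table=tab, isolated=[])
        with pytest.raises(ValueError, match="no node survives"):
            tc.threshold_directed_subnetwork(g, prof, fraction=1.0,
                                             mode="all")


class TestMCODE:
    def test_lone_triangle_is_one_module(self):
        g = nx.cycle_graph(3)
        mods = tc.mcode_modules(g)
        assert len(mods) == 1
        assert sorted(mods[0].members) == [0, 1, 2]
        assert mods[0].score == pytest.approx(3.0)  # density 1 x size 3

    def test_edgeless_graph_no_modules(self):
        g = nx.empty_graph(5)
        assert tc.mcode_modules(g) == []

    def test_planted_clique_is_top_module(self, interactome_data):
        g, _, module = interactome_data
        mods = tc.mcode_modules(g)
        assert mods, "expected at least one module"
        assert set(mods[0].members) >= module

    def test_modules_node_disjoint_and_connected(self, interactome_data):
        g, _, _ = interactome_data
        mods = tc.mcode_modules(g)
        seen = set()
        for m in mods:
            assert not (set(m.members) & seen)
            seen |= set(m.members)
            assert nx.is_connected(g.subgraph(m.members))
            assert m.score > 0

    def test_haircut_trims_pendant_node(self):
        g = nx.complete_graph(4)
        g.add_edge(0, "tail")
        mods = tc.mcode_modules(g, haircut=True)
        assert "tail" not in mods[0].members
        assert sorted(mods[0].members) == [0, 1, 2, 3]

    def test_determinism(self, interactome_data):
        g, _, _ = interactome_data
        m1 = tc.mcode_modules(g)
        m2 = tc.mcode_modules(g)
        assert [m.members for m in m1] == [m.members for m in m2]
        assert [m.score for m in m1] == [m.score for m in m2]
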