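"""Unit tests for co-occurrence networks, modules and Zi/Pi roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilcue import network as net


def table_from_columns(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(
        len(next(iter(cols.values()))))])


class TestPrefilter:
    def test_identity_thresholds(self, rng):
        t = pd.DataFrame(rng.poisson(5, size=(10, 6)),
                         columns=[f"a{i}" for i in range(6)])
        pd.testing.assert_frame_equal(net.prefilter_asvs(t, 0.0, 0.0), t)

    def test_prevalence_rule(self):
        t = pd.DataFrame({"rare": [1] + [0] * 19, "common": [5] * 20})
        out = net.prefilter_asvs(t, min_prevalence=0.2)
        assert list(out.columns) == ["common"]

    def test_never_adds_asvs(self, rng):
        t = pd.DataFrame(rng.poisson(2, size=(12, 8)),
                         columns=[f"a{i}" for i in range(8)])
        out = net.prefilter_asvs(t, 0.3, 0.01)
        assert out.shape[1] <= t.shape[1]

    def test_all_removed_errors(self):
        t = pd.DataFrame({"a": [1, 0, 0, 0, 0]})
        with pytest.raises(ValueError):
            net.prefilter_asvs(t, min_prevalence=0.9)


class TestSpearmanNetwork:
    def test_perfect_concordance_kept(self):
        base = np.arange(10, dtype=float)
        t = table_from_columns({"a": base, "b": base * 2 + 1, "c": base[::-1]})
        g = net.spearman_network(t)
        assert g.graph.has_edge("a", "b")
        assert g.graph["a"]["b"]["r"] == pytest.approx(1.0)
        assert g.graph.has_edge("a", "c")  # |r| = 1 on reversed ranks
        assert g.graph["a"]["c"]["r"] == pytest.approx(-1.0)

    def test_joint_threshold_drops_insignificant(self):
        # n=4: even r=0.8 has p well above 0.05
        t = table_from_columns({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 4, 3],
                                "c": [4.0, 1, 3, 2]})
        g = net.spearman_network(t, r_min=0.75, alpha=0.05)
        assert g.graph.number_of_edges() == 0

    def test_constant_column_excluded(self, rng):
        t = table_from_columns({"a": rng.normal(size=8),
                                "flat": np.ones(8)})
        g = net.spearman_network(t)
        assert g.graph.degree("flat") == 0

    def test_matches_rank_pearson_oracle(self, rng):
        """Spearman r equals Pearson on ranks for tie-free vectors."""
        for _ in range(20):
            a, b = rng.normal(size=(2, 9))
            expected = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
            assert stats.spearmanr(a, b).statistic == pytest.approx(
                expected, rel=1e-12)

    def test_too_few_sites(self):
        t = table_from_columns({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            net.spearman_network(t)


def clique_graph(cliques: list[list[str]], bridges=()) -> net.CooccurrenceNetwork:
    G = nx.Graph()
    for members in cliques:
        G.add_edges_from(itertools.combinations(members, 2))
    G.add_edges_from(bridges)
    edges = pd.DataFrame([{"node1": u, "node2": v, "r": 1.0, "p": 0.0}
                          for u, v in G.edges])
    return net.CooccurrenceNetwork(graph=G, edges=edges)


class TestModules:
    def test_disjoint_cliques(self):
        g = clique_graph([[f"a{i}" for i in range(4)],
                          [f"b{i}" for i in range(4)]])
        part = net.detect_modules(g)
        assert len(set(part.values())) == 2
        assert len({part[f"a{i}"] for i in range(4)}) == 1

    def test_ring_of_cliques(self):
        """Four 5-cliques joined in a ring resolve to the four cliques."""
        cliques = [[f"c{k}_{i}" for i in range(5)] for k in range(4)]
        bridges = [(cliques[k][0], cliques[(k + 1) % 4][1]) for k in range(4)]
        g = clique_graph(cliques, bridges)
        part = net.detect_modules(g)
        assert len(set(part.values())) == 4
        for members in cliques:
            assert len({part[m] for m in members}) == 1
        # the clique partition beats the all-in-one partition
        communities = [{n for n, m in part.items() if m == mod}
                       for mod in set(part.values())]
        q = nx.community.modularity(g.graph, communities)
        assert q > 0.0

    def test_labels_by_descending_size(self):
        g = clique_graph([["a", "b"], ["x", "y", "z"]])
        part = net.detect_modules(g)
        assert part["x"] == "Mod#0"  # larger module first
        assert part["a"] == "Mod#1"

    def test_isolated_nodes_are_singletons(self):
        g = clique_graph([["a", "b", "c"]])
        g.graph.add_node("lonely")
        part = net.detect_modules(g)
        assert part["lonely"] != part["a"]

    def test_deterministic(self, rng):
        t = pd.DataFrame(rng.normal(size=(12, 15)),
                         columns=[f"a{i}" for i in range(15)])
        g1 = net.spearman_network(t, r_min=0.3, alpha=0.5)
        g2 = net.spearman_network(t, r_min=0.3, alpha=0.5)
        assert net.detect_modules(g1) == net.detect_modules(g2)


class TestZiPi:
    def test_all_edges_within_module_pi_zero(self):
        g = clique_graph([["a", "b", "c", "d"]])
        part = net.detect_modules(g)
        topo = net.compute_zi_pi(g, part)
        assert (topo["pi"] == 0.0).all()

    def test_even_split_pi_half(self):
        """Degree 4 split evenly over 2 modules: Pi = 1 − 2·0.25 = 0.5."""
        g = clique_graph([["a1", "a2", "a3"], ["b1", "b2", "b3"]],
                         bridges=[("hub", "a1"), ("hub", "a2"),
                                  ("hub", "b1"), ("hub", "b2")])
        part = {n: "A" for n in ["a1", "a2", "a3"]}
        part.update({n: "B" for n in ["b1", "b2", "b3"]})
        part["hub"] = "A"
        topo = net.compute_zi_pi(g, part)
        # hub has 2 edges into A and 2 into B
        assert topo.loc["hub", "pi"] == pytest.approx(0.5)

    def test_degree_conservation(self, default_study):
        """Within- plus among-module degree equals total degree."""
        table = net.prefilter_asvs(default_study.asv_bacteria, 0.2)
        g = net.spearman_network(table)
        part = net.detect_modules(g)
        topo = net.compute_zi_pi(g, part)
        for node in list(g.graph.nodes)[:20]:
            per_mod = {}
            for nb in g.graph.neighbors(node):
                per_mod[part[nb]] = per_mod.get(part[nb], 0) + 1
            assert sum(per_mod.values()) == g.graph.degree(node)
        assert ((topo["pi"] >= 0) & (topo["pi"] < 1)).all()

    def test_mean_node_zi_zero(self):
        g = clique_graph([["a", "b", "c", "d"]])
        part = net.detect_modules(g)
        topo = net.compute_zi_pi(g, part)
        # clique: every node at the module mean -> Zi = 0
        assert (topo["zi"] == 0.0).all()


class TestRoles:
    @pytest.mark.parametrize("zi,pi,expected", [
        (3.0, 0.1, "module hub"),
        (1.0, 0.7, "connector"),
        (3.0, 0.7, "network hub"),
        (1.0, 0.1, "peripheral"),
    ])
    def test_rule(self, zi, pi, expected):
        topo = pd.DataFrame({"zi": [zi], "pi": [pi]}, index=["n"])
        assert net.classify_roles(topo).loc["n"] == expected


class TestModuleFactorCorrelation:
    def test_closure(self, default_study):
        """Total-partition module abundances sum to 1 at every site."""
        table = default_study.asv_bacteria
        part = {a: f"M{i % 3}" for i, a in enumerate(table.columns)}
        ab = net.module_abundance(table, part)
        assert np.allclose(ab.sum(axis=1), 1.0)

    def test_rank_identical_factor(self, rng):
        table = pd.DataFrame(rng.poisson(20, size=(12, 4)) + 1,
                             columns=list("abcd"),
                             index=[f"s{i}" for i in range(12)])
        part = {a: "M0" for a in "ab"} | {a: "M1" for a in "cd"}
        ab = net.module_abundance(table, part)
        factors = pd.DataFrame({"f": ab["M0"]})
        res = net.module_factor_correlation(table, part, factors)
        row = res[(res.module == "M0") & (res.factor == "f")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_single_module_flagged_nan(self, rng):
        table = pd.DataFrame(rng.poisson(20, size=(10, 3)) + 1,
                             columns=list("abc"),
                             index=[f"s{i}" for i in range(10)])
        part = {a: "M0" for a in "abc"}
        factors = pd.DataFrame({"f": rng.normal(size=10)}, index=table.index)
        res = net.module_factor_correlation(table, part, factors)
        assert np.isnan(res["r"].iloc[0])
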