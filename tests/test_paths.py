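"""Terminal detection, simple-path enumeration, and pathway filtering."""

import numpy as np
import pytest

from conftest import build_net, chain_net, dag_path_count, dfs_simple_paths
from pathminer.errors import AnnotationMissingError
from pathminer.paths import (
    RegulatoryPath,
    enumerate_paths,
    filter_potential_active,
    find_terminals,
    is_potential_active,
)
from pathminer.subnetwork import NodeAnnotation


def annotations(de="", expressed="", nodes=""):
    """Annotation map over single-character node ids."""
    de, expressed, nodes = set(de), set(expressed), set(nodes)
    return {
        n: NodeAnnotation(n, n in de, n in expressed | de, False)
        for n in nodes | de | expressed
    }


class TestRegulatoryPath:
    def test_length_counts_nodes(self):
        assert len(RegulatoryPath(("a", "b", "c"))) == 3

    def test_repeated_node_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            RegulatoryPath(("a", "b", "a"))


class TestFindTerminals:
    def test_chain(self):
        sources, sinks = find_terminals(chain_net("A", "B", "C"))
        assert sources == {"A"} and sinks == {"C"}

    def test_two_cycle_has_no_terminals(self):
        net = build_net({"A": "TF", "B": "miRNA"}, [("A", "B"), ("B", "A")])
        assert find_terminals(net) == (set(), set())

    def test_multi_root_dag_matches_degree_tally(self):
        edges = [("r1", "x"), ("r2", "x"), ("r3", "y"), ("x", "l1"), ("y", "l2"), ("x", "l2")]
        net = build_net({n: "TF" for n in "x y r1 r2 r3 l1 l2".split()}, edges)
        sources, sinks = find_terminals(net)
        # oracle: explicit degree tally
        indeg = {n: 0 for n in net.node_ids}
        outdeg = {n: 0 for n in net.node_ids}
        for u, v in edges:
            outdeg[u] += 1
            indeg[v] += 1
        assert sources == {n for n, d in indeg.items() if d == 0} == {"r1", "r2", "r3"}
        assert sinks == {n for n, d in outdeg.items() if d == 0} == {"l1", "l2"}


class TestEnumerate:
    def test_triangle_shortcut(self):
        net = build_net({"S": "TF", "A": "TF", "T": "gene"},
                        [("S", "A"), ("A", "T"), ("S", "T")])
        res = enumerate_paths(net)
        assert {p.nodes for p in res} == {("S", "A", "T"), ("S", "T")}

    def test_diamond_has_two_paths(self):
        net = build_net({n: "TF" for n in "SABT"},
                        [("S", "A"), ("A", "T"), ("S", "B"), ("B", "T")])
        assert len(enumerate_paths(net)) == 2

    def test_cycle_graph_paths_are_simple_and_match_oracle(self):
        edges = [("S", "A"), ("A", "B"), ("B", "A"), ("B", "T"), ("A", "T")]
        net = build_net({n: "miRNA" if n in "AB" else "TF" for n in "SABT"}, edges)
        res = enumerate_paths(net)
        for p in res:
            assert len(set(p.nodes)) == len(p.nodes)
        assert {p.nodes for p in res} == dfs_simple_paths(set(edges), {"S"}, {"T"})

    def test_deterministic_lexicographic_order(self):
        net = build_net({n: "TF" for n in "SABT"},
                        [("S", "B"), ("S", "A"), ("A", "T"), ("B", "T")])
        res = enumerate_paths(net)
        assert [p.nodes for p in res] == [("S", "A", "T"), ("S", "B", "T")]

    def test_max_len_caps_node_count(self):
        net = chain_net("A", "B", "C", "D")
        res = enumerate_paths(net, max_len=3)
        assert res.paths == []  # the only terminal path has 4 nodes

    def test_max_paths_sets_truncation_flag(self):
        net = build_net({n: "TF" for n in "SABT"},
                        [("S", "A"), ("A", "T"), ("S", "B"), ("B", "T")])
        res = enumerate_paths(net, max_paths=1)
        assert len(res) == 1 and res.truncated

    def test_invalid_caps_rejected(self):
        net = chain_net("A", "B")
        with pytest.raises(ValueError):
            enumerate_paths(net, max_paths=0)
        with pytest.raises(ValueError):
            enumerate_paths(net, max_len=1)

    def test_random_graphs_match_exhaustive_dfs_and_dag_count(self):
        rng = np.random.default_rng(2024)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            density = rng.uniform(0.1, 0.4)
            nodes = [f"n{i}" for i in range(n)]
            edges = {
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < density
            }
            net = build_net({v: "TF" for v in nodes}, edges)
            sources, sinks = find_terminals(net)
            res = enumerate_paths(net, max_len=n)
            got = {p.nodes for p in res}
            assert got == dfs_simple_paths(edges, sources, sinks, max_len=n)
            # second oracle on acyclic instances: DP path count
            dag_edges = {(u, v) for u, v in edges if u < v}
            dag = build_net({v: "TF" for v in nodes}, dag_edges)
            dag_sources, dag_sinks = find_terminals(dag)
            dag_res = enumerate_paths(dag, max_len=n)
            assert not res.truncated and not dag_res.truncated
            assert len(dag_res) == dag_path_count(dag_edges, dag_sources, dag_sinks)


class TestFilter:
    def path(self, *nodes):
        return RegulatoryPath(tuple(nodes))

    def test_single_gap_between_de_nodes_retained(self):
        ann = annotations(de="ac", expressed="b")
        assert is_potential_active(self.path("a", "b", "c"), ann)

    def test_double_gap_between_de_nodes_rejected(self):
        ann = annotations(de="ad", expressed="bc")
        assert not is_potential_active(self.path("a", "b", "c", "d"), ann)

    def test_two_node_path_rejected(self):
        ann = annotations(de="a", expressed="b")
        assert not is_potential_active(self.path("a", "b"), ann)

    def test_no_de_node_rejected(self):
        ann = annotations(expressed="abc")
        assert not is_potential_active(self.path("a", "b", "c"), ann)

    def test_unmeasured_node_counts_as_gap(self):
        # b and c lack expression entirely: run of 2 between DE endpoints
        ann = annotations(de="ad", nodes="bc")
        assert not is_potential_active(self.path("a", "b", "c", "d"), ann)

    def test_terminal_rule_internal_vs_all_runs(self):
        ann = annotations(de="c", expressed="ab")
        p = self.path("a", "b", "c")
        assert is_potential_active(p, ann, terminal_rule="internal_only")
        assert not is_potential_active(p, ann, terminal_rule="all_runs")

    def test_min_de_nodes_config(self):
        ann = annotations(de="a", expressed="bc")
        p = self.path("a", "b", "c")
        assert is_potential_active(p, ann, min_de_nodes=1)
        assert not is_potential_active(p, ann, min_de_nodes=2)

    def test_unannotated_node_names_it(self):
        ann = annotations(de="ab")
        with pytest.raises(AnnotationMissingError, match="zz"):
            is_potential_active(self.path("a", "b", "zz"), ann)

    def test_filter_is_pure_and_idempotent(self):
        ann = annotations(de="ace", expressed="bdf")
        paths = [
            self.path("a", "b", "c"),
            self.path("a", "b"),
            self.path("b", "d", "f"),
            self.path("a", "b", "d", "e"),
        ]
        once = filter_potential_active(paths, ann)
        assert set(p.nodes for p in once) <= set(p.nodes for p in paths)
        assert filter_potential_active(once, ann) == once
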