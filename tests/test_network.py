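"""Network construction, centralities vs brute-force oracle, key calling."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirtfnet.correlation import EDGE_COLUMNS
from mirtfnet.network import (
    betweenness,
    betweenness_bruteforce,
    build_network,
    degree,
    export_network,
    key_elements,
    network_to_edge_table,
    read_graphml_network,
)


def _edges(rows):
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def _de(entities):
    return pd.DataFrame(
        {
            "entity": entities,
            "role": ["TF" if e.startswith("TF") else
                     "miRNA" if e.startswith("miR") else "gene" for e in entities],
            "comparison": "primary_vs_normal",
            "lfc": np.linspace(-2, 2, len(entities)),
            "t_stat": 0.0, "p_value": 0.5, "adj_p": 0.5,
            "is_de": True, "direction": "up", "degenerate": False,
        }
    )


def _toy_graph(edge_pairs):
    g = nx.Graph()
    for u, v in edge_pairs:
        g.add_edge(u, v)
    return g


class TestBuild:
    def test_disjoint_edge_sets_union_nodes(self):
        tf = _edges([("TF1", "TF", "G1", 0.8, 0.001, 1, 0.8)])
        mir = _edges([("miR1", "miRNA", "G2", -0.7, 0.001, -1, 0.7)])
        g = build_network(tf, mir, _de(["TF1", "G1", "miR1", "G2"]), "primary_vs_normal")
        assert set(g.nodes) == {"TF1", "G1", "miR1", "G2"}
        assert g.number_of_edges() == 2
        assert g.nodes["TF1"]["role"] == "TF"
        assert g.nodes["miR1"]["role"] == "miRNA"

    def test_duplicate_edge_keeps_max_abs_pcc(self):
        tf = _edges(
            [
                ("TF1", "TF", "G1", 0.5, 0.01, 1, 0.5),
                ("TF1", "TF", "G1", 0.6, 0.01, 1, 0.6),
            ]
        )
        g = build_network(tf, _edges([]), _de(["TF1", "G1"]), "s")
        assert g.number_of_edges() == 1
        assert g["TF1"]["G1"]["pcc"] == pytest.approx(0.6)

    def test_endpoint_without_de_annotation_errors(self):
        tf = _edges([("TF1", "TF", "G1", 0.8, 0.001, 1, 0.8)])
        with pytest.raises(ValueError, match="DE annotation"):
            build_network(tf, _edges([]), _de(["TF1"]), "s")

    def test_self_loop_rejected(self):
        tf = _edges([("TF1", "TF", "TF1", 0.8, 0.001, 1, 0.8)])
        with pytest.raises(ValueError, match="self-loop"):
            build_network(tf, _edges([]), _de(["TF1"]), "s")

    def test_node_lfc_attached(self):
        tf = _edges([("TF1", "TF", "G1", 0.8, 0.001, 1, 0.8)])
        de = _de(["TF1", "G1"])
        g = build_network(tf, _edges([]), de, "s")
        assert g.nodes["G1"]["lfc"] == pytest.approx(
            float(de.set_index("entity").loc["G1", "lfc"])
        )


class TestDegree:
    def test_star(self):
        g = _toy_graph([("c", f"l{i}") for i in range(6)])
        d = degree(g)
        assert d["c"] == 6 and all(d[f"l{i}"] == 1 for i in range(6))

    def test_triangle(self):
        g = _toy_graph([("a", "b"), ("b", "c"), ("c", "a")])
        assert set(degree(g).values()) == {2}

    def test_empty_edge_set(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert set(degree(g).values()) == {0}


class TestBetweenness:
    def test_path_graph(self):
        g = _toy_graph([("A", "B"), ("B", "C")])
        bc = betweenness(g)
        assert bc["B"] == pytest.approx(1.0)
        assert bc["A"] == bc["C"] == 0.0

    def test_four_cycle(self):
        g = _toy_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        bc = betweenness(g)
        for v in "abcd":
            assert bc[v] == pytest.approx(0.5 / 3)

    def test_star_center_one_leaves_zero(self):
        g = _toy_graph([("c", f"l{i}") for i in range(8)])
        bc = betweenness(g)
        assert bc["c"] == pytest.approx(1.0)
        assert all(bc[f"l{i}"] == 0.0 for i in range(8))

    def test_fewer_than_three_nodes_degenerate_zero(self):
        g = _toy_graph([("a", "b")])
        assert set(betweenness(g).values()) == {0.0}

    def test_bruteforce_matches_fixtures(self):
        g = _toy_graph([("A", "B"), ("B", "C")])
        assert betweenness_bruteforce(g)["B"] == pytest.approx(1.0)
        star = _toy_graph([("c", f"l{i}") for i in range(5)])
        assert betweenness_bruteforce(star)["c"] == pytest.approx(1.0)

    def test_disconnected_two_triangles(self):
        g = _toy_graph(
            [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]
        )
        bf = betweenness_bruteforce(g)
        assert set(bf.values()) == {0.0}
        assert betweenness(g) == pytest.approx(bf)

    def test_size_guard(self):
        g = nx.path_graph(20)
        with pytest.raises(ValueError, match="brute-force"):
            betweenness_bruteforce(g)

    def test_brandes_equals_bruteforce_on_random_graphs(self):
        """Spot-check the oracle equivalence (the full 100-graph sweep runs
        in the acceptance suite)."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            p = float(rng.uniform(0.15, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            fast = betweenness(g)
            slow = betweenness_bruteforce(g)
            for v in g.nodes:
                assert fast[v] == pytest.approx(slow[v], abs=1e-12)
                assert 0.0 <= fast[v] <= 1.0


class TestKeyElements:
    def _annotated_star(self, k=20):
        g = _toy_graph([("TF1", f"G{i:03d}") for i in range(k)])
        for n in g.nodes:
            g.nodes[n]["role"] = "TF" if n.startswith("TF") else "gene"
            g.nodes[n]["lfc"] = 0.0
        return g

    @pytest.mark.parametrize("rule", ["both", "either"])
    def test_star_center_is_key_leaves_never(self, rule):
        rep = key_elements(self._annotated_star(), rule=rule)
        keys = set(rep.loc[rep["is_key"], "node"])
        assert keys == {"TF1"}

    def test_all_equal_degrees_flag_nothing(self):
        g = _toy_graph([("a", "b"), ("b", "c"), ("c", "a")])
        for n in g.nodes:
            g.nodes[n].update(role="gene", lfc=0.0)
        rep = key_elements(g)
        assert not rep["is_key"].any()
        assert (rep["z_degree"] == 0).all()  # sd = 0 branch

    def test_report_sorted_bc_then_degree_then_id(self):
        rep = key_elements(self._annotated_star())
        assert rep.loc[0, "node"] == "TF1"
        leaves = rep["node"].tolist()[1:]
        assert leaves == sorted(leaves)

    def test_degree_sum_is_twice_edges(self):
        g = self._annotated_star(9)
        rep = key_elements(g)
        assert rep["degree"].sum() == 2 * g.number_of_edges()

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            key_elements(self._annotated_star(), rule="any")


class TestExport:
    def _network(self):
        tf = _edges([("TF1", "TF", "G1", 0.8, 0.001, 1, 0.8)])
        mir = _edges([("miR1", "miRNA", "G1", -0.6, 0.002, -1, 0.6)])
        return build_network(tf, mir, _de(["TF1", "G1", "miR1"]), "primary_vs_normal")

    def test_empty_network_header_only_tsv_and_empty_sif(self, tmp_path):
        g = build_network(_edges([]), _edges([]), _de(["TF1"]), "s")
        tsv = tmp_path / "e.tsv"
        sif = tmp_path / "e.sif"
        export_network(g, str(tsv), "tsv")
        export_network(g, str(sif), "sif")
        assert tsv.read_text().strip() == "\t".join(EDGE_COLUMNS)
        assert sif.read_text() == ""

    def test_sif_lines(self, tmp_path):
        path = tmp_path / "n.sif"
        export_network(self._network(), str(path), "sif")
        lines = path.read_text().strip().splitlines()
        assert lines == ["TF1\tactivates\tG1", "miR1\trepresses\tG1"]

    def test_graphml_round_trip(self, tmp_path):
        g = self._network()
        path = tmp_path / "n.graphml"
        export_network(g, str(path), "graphml")
        back = read_graphml_network(str(path))
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for n in g.nodes:
            assert back.nodes[n]["role"] == g.nodes[n]["role"]
            assert back.nodes[n]["lfc"] == pytest.approx(g.nodes[n]["lfc"])
        for u, v in g.edges:
            assert back[u][v]["pcc"] == pytest.approx(g[u][v]["pcc"])
            assert back[u][v]["sign"] == g[u][v]["sign"]

    def test_edge_table_mirrors_records(self):
        table = network_to_edge_table(self._network())
        assert list(table.columns) == EDGE_COLUMNS
        assert set(table["regulator"]) == {"TF1", "miR1"}

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(self._network(), str(tmp_path / "x"), "xlsx")
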