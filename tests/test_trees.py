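import json

import networkx as nx
import pytest

from dxpath.features import build_vocabulary, encode_triplet
from dxpath.trees import (
    CoverageResult,
    DiseaseTreeNode,
    build_temporal_network,
    build_trees,
    covers,
    cumulative_coverage,
    export_graph,
    pathways_from_final_model,
    rank_children,
    rank_forest,
    retain_parents,
)

from conftest import make_timeline


class TestPathwaysFromFinalModel:
    def test_full_key_set_maps_to_its_triplet(self):
        vocab = build_vocabulary({("A", "B", "C")})
        keys = list(encode_triplet(("A", "B", "C")))
        assert pathways_from_final_model(keys, vocab) == {("A", "B", "C")}

    def test_shared_key_maps_to_all_generators(self):
        trips = {("A", "B", "C"), ("C", "A", "B")}
        vocab = build_vocabulary(trips)
        ab = [k for k in vocab.keys if k.group == 6 and k.token == "A&B"]
        assert pathways_from_final_model(ab, vocab) == trips

    def test_empty_selection_gives_empty_set(self):
        vocab = build_vocabulary({("A", "B", "C")})
        assert pathways_from_final_model([], vocab) == set()


@pytest.fixture
def eight_timelines():
    return [
        make_timeline("c1", [("A", 1), ("B", 2), ("C", 3)], is_case=True),
        make_timeline("c2", [("A", 1), ("B", 2), ("D", 3)], is_case=True),
        make_timeline("c3", [("A", 1), ("E", 2), ("F", 3)], is_case=True),
        make_timeline("c4", [("A", 1), ("B", 2)], is_case=True),
        make_timeline("k1", [("A", 1), ("B", 2), ("C", 3)], is_case=False),
        make_timeline("k2", [("B", 1), ("A", 2), ("C", 3)], is_case=False),
        make_timeline("k3", [("A", 1), ("C", 2)], is_case=False),
        make_timeline("k4", [], is_case=False),
    ]


class TestBuildTrees:
    TRIPS = {("A", "B", "C"), ("A", "B", "D"), ("A", "E", "F")}

    def test_prefix_merge_structure(self, eight_timelines):
        forest = build_trees(self.TRIPS, eight_timelines)
        assert set(forest) == {"A"}
        root = forest["A"]
        assert set(root.children) == {"B", "E"}
        assert set(root.children["B"].children) == {"C", "D"}
        assert set(root.children["E"].children) == {"F"}
        assert root.level == 1 and root.children["B"].level == 2
        assert root.children["B"].children["C"].level == 3

    def test_disjoint_roots_give_one_tree_each(self, eight_timelines):
        forest = build_trees({("A", "B", "C"), ("X", "Y", "Z")}, eight_timelines)
        assert set(forest) == {"A", "X"}

    def test_coverage_counts_match_brute_force(self, eight_timelines):
        forest = build_trees(self.TRIPS, eight_timelines)

        def brute(path):
            hits_all, hits_case = set(), set()
            for tl in eight_timelines:
                if covers(tl.date_of(), path):
                    hits_all.add(tl.person_id)
                    if tl.is_case:
                        hits_case.add(tl.person_id)
            return hits_all, hits_case

        root = forest["A"]
        checks = [
            (("A",), root),
            (("A", "B"), root.children["B"]),
            (("A", "B", "C"), root.children["B"].children["C"]),
            (("A", "E"), root.children["E"]),
            (("A", "E", "F"), root.children["E"].children["F"]),
        ]
        for path, node in checks:
            hits_all, hits_case = brute(path)
            assert node.covered_all == hits_all, path
            assert node.covered_cases == hits_case, path

    def test_child_coverage_is_subset_of_parent(self, eight_timelines):
        forest = build_trees(self.TRIPS, eight_timelines)
        for root in forest.values():
            for child in root.children.values():
                assert child.covered_all <= root.covered_all
                for leaf in child.children.values():
                    assert leaf.covered_all <= child.covered_all

    def test_dementia_probability_from_counts(self, eight_timelines):
        forest = build_trees(self.TRIPS, eight_timelines)
        node = forest["A"].children["B"].children["C"]
        # covered by c1 (case) and k1 (control); k2 has B before A
        assert node.covered_all == {"c1", "k1"}
        assert node.dementia_probability == pytest.approx(0.5)


def _node(cat, prob_pairs, level=2):
    """Node whose dementia probability is n_case/(n_case+n_ctrl)."""
    n_case, n_total = prob_pairs
    node = DiseaseTreeNode(cat, level)
    node.covered_cases = {f"{cat}_c{i}" for i in range(n_case)}
    node.covered_all = node.covered_cases | {f"{cat}_k{i}" for i in range(n_total - n_case)}
    return node


class TestRankChildren:
    def test_fewer_than_k_children_all_kept(self):
        root = DiseaseTreeNode("R", 1)
        root.children = {c: _node(c, (1, 2)) for c in "ABC"}
        assert set(rank_children(root, k=5).children) == {"A", "B", "C"}

    def test_top_five_probabilities_kept(self):
        probs = {"A": 9, "B": 8, "C": 7, "D": 6, "E": 5, "F": 4}
        root = DiseaseTreeNode("R", 1)
        root.children = {c: _node(c, (p, 10)) for c, p in probs.items()}
        assert set(rank_children(root, k=5).children) == {"A", "B", "C", "D", "E"}

    def test_probability_tie_broken_by_case_count(self):
        root = DiseaseTreeNode("R", 1)
        root.children = {
            "W": _node("W", (9, 10)),
            "X": _node("X", (40, 50)),  # tied 0.8 with Y
            "Y": _node("Y", (60, 75)),
        }
        kept = rank_children(root, k=2).children
        assert set(kept) == {"W", "Y"}  # Y beats X on case count


class TestCumulativeCoverage:
    @staticmethod
    def _forest(sets):
        forest = {}
        for cat, ids in sets.items():
            node = DiseaseTreeNode(cat, 1)
            node.covered_cases = set(ids)
            node.covered_all = set(ids)
            forest[cat] = node
        return forest

    def test_greedy_order_and_curve(self):
        # brute-force unions: P1 covers 30/50; P3 then adds 11 new cases
        # ({35..45}), beating P2's 10 ({31..40}); P2 finally adds {31..34}
        forest = self._forest(
            {
                "P1": set(range(1, 31)),
                "P2": set(range(20, 41)),
                "P3": set(range(35, 46)),
            }
        )
        cov = cumulative_coverage(forest, set(range(1, 51)))
        assert cov.parent_order == ["P1", "P3", "P2"]
        assert cov.curve == pytest.approx([0.60, 0.82, 0.90])
        assert cov.marginal_cases == [30, 11, 4]

    def test_marginal_gains_are_nonincreasing(self):
        forest = self._forest({"A": {1, 2, 3}, "B": {2, 3, 4, 5}, "C": {6}})
        cov = cumulative_coverage(forest, set(range(1, 8)))
        assert all(a >= b for a, b in zip(cov.marginal_cases, cov.marginal_cases[1:]))
        assert all(x <= y for x, y in zip(cov.curve, cov.curve[1:]))
        assert cov.curve[-1] <= 1.0

    def test_single_parent_covering_all_is_chosen(self):
        forest = self._forest({"P": {1, 2, 3}})
        cov = cumulative_coverage(forest, {1, 2, 3})
        assert cov.curve == [1.0] and cov.chosen_count == 1

    def test_zero_gain_parent_not_chosen(self):
        forest = self._forest({"A": {1, 2, 3}, "B": {1, 2}})
        cov = cumulative_coverage(forest, {1, 2, 3})
        assert cov.chosen_count == 1 and len(cov.parent_order) == 2

    def test_empty_forest_gives_empty_curve(self):
        cov = cumulative_coverage({}, {1, 2})
        assert cov.curve == [] and cov.chosen_count == 0

    def test_retain_parents_restricts_forest(self):
        forest = self._forest({"A": {1, 2, 3}, "B": {1, 2}})
        cov = cumulative_coverage(forest, {1, 2, 3})
        assert set(retain_parents(forest, cov)) == {"A"}


def _forest_with_paths(paths):
    """Forest from {(d1,d2,d3): n_covering_cases}."""
    forest = {}
    for (d1, d2, d3), n in paths.items():
        root = forest.setdefault(d1, DiseaseTreeNode(d1, 1))
        child = root.children.setdefault(d2, DiseaseTreeNode(d2, 2))
        leaf = child.children.setdefault(d3, DiseaseTreeNode(d3, 3))
        leaf.covered_cases = {f"{d1}{d2}{d3}_{i}" for i in range(n)}
        leaf.covered_all = set(leaf.covered_cases)
    return forest


class TestTemporalNetwork:
    def test_threshold_drops_thin_pathways(self):
        forest = _forest_with_paths({("A", "B", "C"): 60, ("X", "Y", "Z"): 40})
        g = build_temporal_network(forest, min_cases=50)
        assert set(g.edges) == {("A", "B"), ("B", "C")}
        assert g.edges["A", "B"]["weight"] == 60

    def test_aggregation_happens_before_threshold(self):
        forest = _forest_with_paths({("A", "B", "C"): 30, ("A", "B", "D"): 30})
        g = build_temporal_network(forest, min_cases=50)
        assert ("A", "B") in g.edges and g.edges["A", "B"]["weight"] == 60
        assert ("B", "C") not in g.edges  # only 30 cases each

    def test_empty_forest_gives_empty_network(self):
        g = build_temporal_network({}, min_cases=50)
        assert g.number_of_edges() == 0

    def test_thresholding_is_idempotent_and_weights_bounded(self):
        forest = _forest_with_paths(
            {("A", "B", "C"): 55, ("A", "B", "D"): 10, ("E", "F", "G"): 52}
        )
        g_all = build_temporal_network(forest, min_cases=0)
        g_thr = build_temporal_network(forest, min_cases=50)
        assert all(d["weight"] >= 50 for _, _, d in g_thr.edges(data=True))
        refiltered = nx.DiGraph(
            (u, v, d) for u, v, d in g_all.edges(data=True) if d["weight"] >= 50
        )
        assert set(refiltered.edges) == set(g_thr.edges)

    def test_no_self_loops(self):
        forest = _forest_with_paths({("A", "B", "C"): 60, ("B", "C", "A"): 60})
        g = build_temporal_network(forest, min_cases=1)
        assert all(u != v for u, v in g.edges)


class TestExportGraph:
    def test_graphml_round_trip(self, tmp_path):
        forest = _forest_with_paths({("A", "B", "C"): 60, ("A", "B", "D"): 55})
        g = build_temporal_network(forest, min_cases=50)
        path = export_graph(g, "graphml", tmp_path / "net.graphml")
        back = nx.read_graphml(path)
        assert set(back.edges) == {(u, v) for u, v in g.edges}
        for u, v in g.edges:
            assert back.edges[u, v]["weight"] == g.edges[u, v]["weight"]

    def test_dot_counts_match_structure(self, tmp_path):
        forest = _forest_with_paths({("A", "B", "C"): 60})
        g = build_temporal_network(forest, min_cases=1)
        path = export_graph(g, "dot", tmp_path / "net.dot")
        text = path.read_text()
        assert text.count("->") == g.number_of_edges()
        node_lines = [l for l in text.splitlines() if "category_class" in l or ("[" in l and "->" not in l)]
        assert len(node_lines) == g.number_of_nodes()

    def test_tree_json_mirrors_memory(self, tmp_path, eight_timelines):
        forest = build_trees({("A", "B", "C")}, eight_timelines)
        path = export_graph(forest, "json", tmp_path / "trees.json")
        payload = json.loads(path.read_text())
        assert payload["A"]["category"] == "A"
        assert payload["A"]["children"][0]["children"][0]["category"] == "C"
        node = forest["A"].children["B"].children["C"]
        assert payload["A"]["children"][0]["children"][0]["n_cases_covered"] == node.n_cases_covered

    def test_coverage_csv(self, tmp_path):
        cov = CoverageResult(["A", "B"], [0.5, 0.75], [10, 5], 2)
        path = export_graph(cov, "csv", tmp_path / "curve.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3

    def test_unknown_format_lists_supported(self, tmp_path):
        with pytest.raises(ValueError, match="graphml"):
            export_graph(nx.DiGraph(), "gexf", tmp_path / "x")


def test_rank_forest_applies_to_all_roots(eight_timelines):
    forest = build_trees({("A", "B", "C"), ("A", "B", "D"), ("X", "Y", "Z")}, eight_timelines)
    pruned = rank_forest(forest, k=1)
    assert all(len(n.children) <= 1 for n in pruned.values())
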