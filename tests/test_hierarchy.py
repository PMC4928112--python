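import numpy as np
import pytest

from netclass import (
    AnnotationSets,
    DirectedNetwork,
    NodeClassMap,
    annotation_enrichment,
    class_overlap_analysis,
    fisher_enrichment,
    hierarchy_score,
    layer_enrichment,
    stratify_hierarchy,
)

from _oracles import bh_adjust_oracle, fisher_two_sided_oracle, random_digraph


def planted_three_layer(seed: int, per_layer: int = 10, out_per_node: int = 4):
    """A DAG whose edges all point top -> middle -> bottom."""
    rng = np.random.default_rng(seed)
    layers = [[f"L{k}_{i}" for i in range(per_layer)] for k in range(3)]
    edges = set()
    for k in (0, 1):
        for u in layers[k]:
            for v in rng.choice(layers[k + 1], size=out_per_node, replace=False):
                edges.add((u, str(v)))
    nodes = [v for layer in layers for v in layer]
    return DirectedNetwork.from_edges(edges, extra_nodes=nodes), layers


class TestHierarchyScore:
    def test_counts_strictly_downward_edges(self):
        labels = np.array([0, 1, 2, 2])
        src = np.array([0, 1, 2, 3])
        dst = np.array([1, 2, 3, 0])
        # 0<1 down, 1<2 down, 2==2 not, 2>0 not
        assert hierarchy_score(labels, src, dst) == pytest.approx(0.5)

    def test_edgeless_graph_scores_one(self):
        assert hierarchy_score(np.array([0, 1]), np.array([], dtype=int), np.array([], dtype=int)) == 1.0


class TestStratification:
    def test_recovers_planted_layers(self):
        net, layers = planted_three_layer(seed=0)
        assign = stratify_hierarchy(net, restarts=40, seed=1)
        assert assign.metadata["best_score"] == pytest.approx(1.0)
        for expect, layer_name in zip(layers, ("top", "middle", "bottom")):
            assert assign.layer_nodes(layer_name) == frozenset(expect)

    def test_probabilities_sum_to_one(self):
        net = random_digraph(np.random.default_rng(3), 25, 0.15)
        assign = stratify_hierarchy(net, restarts=9, seed=0)
        sums = assign.table[["p_top", "p_middle", "p_bottom"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_hard_label_requires_majority(self):
        net = random_digraph(np.random.default_rng(4), 25, 0.15)
        assign = stratify_hierarchy(net, restarts=9, seed=0)
        probs = assign.table[["p_top", "p_middle", "p_bottom"]].to_numpy()
        for pmax, layer in zip(probs.max(axis=1), assign.table["layer"]):
            assert (layer == "unassigned") == (pmax <= 0.5)

    def test_best_score_never_below_init(self):
        net = random_digraph(np.random.default_rng(5), 30, 0.1)
        assign = stratify_hierarchy(net, restarts=5, seed=2)
        for rec in assign.metadata["restart_scores"]:
            assert rec["best_score"] >= rec["init_score"]

    def test_deterministic(self):
        net = random_digraph(np.random.default_rng(6), 20, 0.15)
        a = stratify_hierarchy(net, restarts=5, seed=7)
        b = stratify_hierarchy(net, restarts=5, seed=7)
        assert a.table.equals(b.table)

    def test_restart_floor(self):
        net = random_digraph(np.random.default_rng(7), 10, 0.2)
        with pytest.raises(ValueError, match="restarts"):
            stratify_hierarchy(net, restarts=2, seed=0)


class TestFisherEnrichment:
    def test_worked_example(self):
        universe = {f"u{i}" for i in range(100)}
        members = {f"u{i}" for i in range(10)}
        target = {f"u{i}" for i in range(5, 15)}
        r = fisher_enrichment(members, target, universe)
        assert (r.a, r.b, r.c, r.d) == (5, 5, 5, 85)
        assert r.odds_ratio == pytest.approx(17.0)
        assert r.fold == pytest.approx(5.0)
        assert r.p_value == pytest.approx(fisher_two_sided_oracle(5, 5, 5, 85), rel=1e-9)

    def test_independence_fold_one(self):
        universe = {f"u{i}" for i in range(100)}
        members = {f"u{i}" for i in range(10)}
        target = {"u0"} | {f"u{i}" for i in range(50, 59)}
        r = fisher_enrichment(members, target, universe)
        assert r.fold == pytest.approx(1.0)

    def test_infinite_odds_when_nested(self):
        universe = {f"u{i}" for i in range(50)}
        members = {f"u{i}" for i in range(5)}
        r = fisher_enrichment(members, members, universe)
        assert r.odds_ratio == float("inf")
        assert r.p_value < 1e-4

    def test_empty_inputs_raise(self):
        universe = {"a", "b"}
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"a"}, universe)
        with pytest.raises(ValueError):
            fisher_enrichment({"a"}, {"b"}, set())

    def test_subset_check(self):
        with pytest.raises(ValueError, match="subsets"):
            fisher_enrichment({"z"}, {"a"}, {"a", "b"})


class TestOverlapAnalysis:
    def _classes(self, net):
        order = net.node_order()
        return NodeClassMap(
            classes={
                "DTN": frozenset(order[:10]),
                "SMN": frozenset(order[5:15]),
                "GGN": frozenset(order[40:50]),
            },
            universe=net,
        )

    def test_pairwise_counts_and_triple(self):
        net = random_digraph(np.random.default_rng(8), 60, 0.05)
        table, triple = class_overlap_analysis(self._classes(net))
        row = table[(table.class_a == "DTN") & (table.class_b == "SMN")].iloc[0]
        assert row["overlap"] == 5
        assert triple == 0

    def test_disjoint_pair_odds_below_one(self):
        net = random_digraph(np.random.default_rng(9), 60, 0.05)
        table, _ = class_overlap_analysis(self._classes(net))
        row = table[(table.class_a == "DTN") & (table.class_b == "GGN")].iloc[0]
        assert row["overlap"] == 0
        assert row["odds_ratio"] == 0.0

    def test_needs_two_classes(self):
        net = random_digraph(np.random.default_rng(10), 20, 0.1)
        classes = NodeClassMap(classes={"X": frozenset(net.node_order()[:5])}, universe=net)
        with pytest.raises(ValueError, match="2 classes"):
            class_overlap_analysis(classes)


class TestLayerEnrichment:
    def test_class_planted_in_top(self):
        net, layers = planted_three_layer(seed=2)
        classes = NodeClassMap(classes={"DTN": frozenset(layers[0][:6])}, universe=net)
        assign = stratify_hierarchy(net, restarts=12, seed=3)
        table = layer_enrichment(classes, assign)
        top = table[table.layer == "top"].iloc[0]
        bottom = table[table.layer == "bottom"].iloc[0]
        assert top["fold"] > 1.0 and top["p_value"] < 0.05
        assert bottom["overlap"] == 0 and bottom["odds_ratio"] == 0.0


class TestAnnotationEnrichment:
    def _setup(self):
        net = random_digraph(np.random.default_rng(11), 80, 0.05)
        order = net.node_order()
        classes = NodeClassMap(classes={"DTN": frozenset(order[:12])}, universe=net)
        sets = AnnotationSets(sets={
            "hit": frozenset(order[:10]),
            "miss": frozenset(order[40:60]),
            "outside": frozenset(order[20:25] + ["NOT_IN_NET"]),
        })
        return net, classes, sets

    def test_bh_matches_textbook_formula(self):
        _, classes, sets = self._setup()
        table = annotation_enrichment(classes, sets)
        want = bh_adjust_oracle(table["p_value"].to_numpy())
        assert np.allclose(table["p_adjusted"].to_numpy(), want)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()

    def test_outside_members_dropped(self, caplog):
        _, classes, sets = self._setup()
        with caplog.at_level("INFO", logger="netclass.hierarchy"):
            table = annotation_enrichment(classes, sets)
        assert table[table.set == "outside"].iloc[0]["set_size"] == 5
        assert any("outside the network" in r.message for r in caplog.records)

    def test_correction_none(self):
        _, classes, sets = self._setup()
        table = annotation_enrichment(classes, sets, correction="none")
        assert (table["p_adjusted"] == table["p_value"]).all()

    def test_bad_correction(self):
        _, classes, sets = self._setup()
        with pytest.raises(ValueError, match="correction"):
            annotation_enrichment(classes, sets, correction="bonferroni")

    def test_empty_sets_raise(self):
        _, classes, _ = self._setup()
        with pytest.raises(ValueError, match="empty"):
            annotation_enrichment(classes, AnnotationSets(sets={}))
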