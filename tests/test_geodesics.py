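import numpy as np
import pytest

from netclass import (
    DirectedNetwork,
    all_geodesics,
    geodesic_ratio,
    gr_difference,
    mean_geodesic_distributions,
    nearest_geodesic_pair,
    nearest_geodesic_vectors,
    reachability_fractions,
)
from netclass.geodesics import gr_difference_from_igraph, odds_ratio_from_counts

from _oracles import floyd_warshall_lengths, random_digraph


class TestAllGeodesics:
    def test_path_forward(self, path3):
        g = all_geodesics(path3, {"A"}, {"C"})
        assert (g.existing, g.possible, g.lengths) == (1, 1, (2,))
        assert g.fraction_existing == 1.0

    def test_path_reverse_unreachable(self, path3):
        g = all_geodesics(path3, {"C"}, {"A"})
        assert (g.existing, g.possible) == (0, 1)
        assert g.fraction_existing == 0.0

    def test_same_node_pairs_excluded(self, cycle3):
        g = all_geodesics(cycle3, {"A", "B"}, {"B", "C"})
        # (A,B), (A,C), (B,C) are possible; (B,B) is not
        assert g.possible == 3
        assert g.lengths == (1, 1, 2)

    def test_unknown_node_raises(self, path3):
        with pytest.raises(ValueError, match="nodes of the network"):
            all_geodesics(path3, {"A"}, {"X"})

    def test_empty_raises(self, path3):
        with pytest.raises(ValueError, match="non-empty"):
            all_geodesics(path3, set(), {"A"})

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            net = random_digraph(rng, int(rng.integers(5, 30)), 0.12)
            order, d = floyd_warshall_lengths(net)
            idx = {v: i for i, v in enumerate(order)}
            nodes = net.node_order()
            src = set(rng.choice(nodes, size=4, replace=False))
            tgt = set(rng.choice(nodes, size=4, replace=False))
            g = all_geodesics(net, src, tgt)
            want = sorted(
                int(d[idx[s], idx[t]])
                for s in src for t in tgt
                if s != t and np.isfinite(d[idx[s], idx[t]])
            )
            assert list(g.lengths) == want


class TestReachability:
    def test_odds_ratio_arithmetic(self):
        # 30/100 existing one way, 20/100 the other: OR = (30/70)/(20/80) = 12/7
        assert odds_ratio_from_counts(30, 70, 20, 80) == pytest.approx(12.0 / 7.0)

    def test_odds_ratio_undefined_on_zero_cell(self):
        assert odds_ratio_from_counts(5, 0, 3, 2) is None
        assert odds_ratio_from_counts(0, 5, 3, 2) is None

    def test_path_classes(self, path3):
        r = reachability_fractions(path3, {"A"}, {"C"})
        assert r.frac_u_to_v == 1.0 and r.frac_v_to_u == 0.0
        assert r.odds_ratio is None

    def test_cycle_symmetric(self, cycle3):
        r = reachability_fractions(cycle3, {"A"}, {"B"})
        assert r.frac_u_to_v == r.frac_v_to_u == 1.0

    def test_overlap_removed(self, cycle3):
        r = reachability_fractions(cycle3, {"A", "B"}, {"B", "C"})
        # counts must involve only A vs C after removing the shared node B
        assert r.exist_uv + r.absent_uv == 1

    def test_identical_classes_raise(self, cycle3):
        with pytest.raises(ValueError, match="identical or empty"):
            reachability_fractions(cycle3, {"A"}, {"A"})


class TestMeanGeodesics:
    def test_cycle_means(self, cycle3):
        res = mean_geodesic_distributions(cycle3, {"A"}, {"B", "C"})
        # A->B = 1, A->C = 2; B->A = 2, C->A = 1
        assert res.per_node.loc[("U", "A"), "mean_out"] == pytest.approx(1.5)
        assert res.per_node.loc[("U", "A"), "mean_in"] == pytest.approx(1.5)
        assert res.pooled_u_to_v == (1, 2)
        assert res.pooled_v_to_u == (1, 2)
        assert res.ranksum_p == pytest.approx(1.0)

    def test_unreachable_gives_nan_mean(self, path3):
        res = mean_geodesic_distributions(path3, {"C"}, {"A"})
        assert np.isnan(res.per_node.loc[("U", "C"), "mean_out"])
        assert res.pooled_u_to_v == ()

    def test_asymmetric_pooled_detected(self):
        # U reaches V in 1 hop; V reaches U only via a long detour
        chain = [("U1", "V1"), ("V1", "x1"), ("x1", "x2"), ("x2", "x3"), ("x3", "U1"),
                 ("U2", "V2"), ("V2", "y1"), ("y1", "y2"), ("y2", "y3"), ("y3", "U2")]
        net = DirectedNetwork.from_edges(chain)
        res = mean_geodesic_distributions(net, {"U1", "U2"}, {"V1", "V2"})
        assert np.mean(res.pooled_u_to_v) < np.mean(res.pooled_v_to_u)
        assert res.ranksum_p < 1.0


class TestNearestVectors:
    def test_cycle_vectors(self, cycle3):
        vec = nearest_geodesic_vectors(cycle3, {"A"}, {"B", "C"})
        assert vec.e_out == {"A": 1}
        assert vec.e_in == {"A": 1}

    def test_overlap_removed_from_both(self, cycle3):
        u, v = nearest_geodesic_pair(cycle3, {"A", "B"}, {"B", "C"}, "U", "V")
        assert u.excluded == frozenset({"B"})
        assert set(u.e_out) == {"A"}
        assert set(v.e_out) == {"C"}
        assert u.e_out["A"] == 2  # A -> B -> C with B removed from U: target C
        assert u.e_in["A"] == 1  # C -> A

    def test_absent_entries_none(self, path3):
        vec = nearest_geodesic_vectors(path3, {"C"}, {"A"})
        assert vec.e_out == {"C": None}
        assert vec.e_in == {"C": 2}
        assert vec.defined_out() == []

    def test_empty_after_overlap_raises(self, cycle3):
        with pytest.raises(ValueError, match="empty after removing"):
            nearest_geodesic_pair(cycle3, {"A"}, {"A", "B"})


class TestGeodesicRatio:
    def test_three_cycle_worked_example(self, cycle3):
        # U = {A}, V = {C}: A->C = 2, C->A = 1 so GR_U = 2, GR_V = 1/2, D = 3/2
        res = gr_difference(cycle3, {"A"}, {"C"}, "U", "V")
        assert res.gr_first == pytest.approx(2.0)
        assert res.gr_second == pytest.approx(0.5)
        assert res.d == pytest.approx(1.5)

    def test_symmetric_positions_give_zero(self):
        net = DirectedNetwork.from_edges(
            [(f"c{i}", f"c{(i + 1) % 6}") for i in range(6)]
        )
        res = gr_difference(net, {"c0"}, {"c3"})
        assert res.d == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(55)
        checked = 0
        for _ in range(20):
            net = random_digraph(rng, 25, 0.15)
            nodes = net.node_order()
            u = set(rng.choice(nodes, size=5, replace=False))
            v = set(rng.choice([x for x in nodes if x not in u], size=5, replace=False))
            try:
                fwd = gr_difference(net, u, v)
                rev = gr_difference(net, v, u)
            except ValueError:
                continue
            assert fwd.d == pytest.approx(-rev.d)
            checked += 1
        assert checked >= 10

    def test_all_absent_raises(self):
        net = DirectedNetwork.from_edges([("x", "y")], extra_nodes=["U1", "V1"])
        u, v = nearest_geodesic_pair(net, {"U1"}, {"V1"})
        with pytest.raises(ValueError, match="all absent"):
            geodesic_ratio(u, v)

    def test_fast_path_matches_reference(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            net = random_digraph(rng, 30, 0.12)
            nodes = net.node_order()
            u = sorted(rng.choice(nodes, size=6, replace=False))
            v = sorted(rng.choice([x for x in nodes if x not in u], size=6, replace=False))
            g = net.to_igraph()
            idx = {nm: i for i, nm in enumerate(g.vs["name"])}
            fast = gr_difference_from_igraph(g, [idx[x] for x in u], [idx[x] for x in v])
            try:
                ref = gr_difference(net, set(u), set(v)).d
            except ValueError:
                assert np.isnan(fast)
                continue
            assert fast == pytest.approx(ref)
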