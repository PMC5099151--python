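"""Network aggregation, degree indices, descriptive statistics, persistence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emonet import (
    CellAgreement,
    CharacterRoster,
    EmotionNetwork,
    ValidationError,
    build_network,
    build_networks,
    cell_observations,
    degree_indices,
    descriptive_stats,
    filter_cells,
    in_out_correlation,
    read_network,
    top_k_table,
    write_network,
)

from conftest import random_network


def agreement(emotion, source, target, retained=True):
    return CellAgreement(emotion, source, target, 0.0, 0.0, 0.0, retained, 1, 0)


def brute_degrees(net):
    """O(n^2) adjacency-matrix oracle for every degree index."""
    names = net.roster.names
    n = len(names)
    w = np.zeros((n, n))
    for (s, t), weight in net.edges.items():
        w[names.index(s), names.index(t)] = weight
    g = (w > 0).astype(int)
    return pd.DataFrame(
        {
            "weighted_indegree": w.sum(axis=0),
            "weighted_outdegree": w.sum(axis=1),
            "weighted_degree": w.sum(axis=0) + w.sum(axis=1),
            "indegree": g.sum(axis=0),
            "outdegree": g.sum(axis=1),
        },
        index=pd.Index(names, name="character"),
    )


class TestBuildNetwork:
    def test_unanimous_cell_any_aggregator(self, small_set):
        cells = [agreement("joy", "Vincent Vega", "Mia Wallace")]
        for agg in ("mean", "median", "sum"):
            net = build_network(cells, small_set, "joy", aggregator=agg)
            expected = 6.0 if agg != "sum" else 18.0
            assert net.edges == {("Vincent Vega", "Mia Wallace"): expected}

    def test_dropped_cell_contributes_no_edge(self, small_set):
        cells = [agreement("joy", "Vincent Vega", "Mia Wallace", retained=False)]
        net = build_network(cells, small_set, "joy")
        assert net.n_edges == 0
        assert net.n_nodes == 3  # roster fixed even with no edges

    def test_mean_weights_match_recomputation(self, small_set):
        cells = filter_cells(cell_observations(small_set), n_boot=200, seed=1)
        nets = build_networks(cells, small_set, aggregator="mean")
        for emotion, net in nets.items():
            for (s, t), w in net.edges.items():
                assert w == pytest.approx(
                    np.mean(small_set.cell_values(emotion, s, t))
                )

    def test_unknown_aggregator(self, small_set):
        with pytest.raises(ValidationError, match="aggregator"):
            build_network([], small_set, "joy", aggregator="mode")

    def test_zero_weight_edges_rejected(self):
        roster = CharacterRoster(("A", "B"))
        with pytest.raises(ValidationError, match="non-positive"):
            EmotionNetwork("fear", roster, {("A", "B"): 0.0})


class TestDegreeIndices:
    def test_empty_network(self):
        net = EmotionNetwork("fear", CharacterRoster(("A", "B")), {})
        assert degree_indices(net).to_numpy().sum() == 0

    def test_worked_example(self):
        roster = CharacterRoster(("A", "B", "C"))
        net = EmotionNetwork(
            "fear", roster, {("A", "B"): 2.0, ("B", "A"): 1.0, ("A", "C"): 4.0}
        )
        t = degree_indices(net)
        assert t.loc["A", "weighted_outdegree"] == 6
        assert t.loc["C", "weighted_indegree"] == 4
        assert t["weighted_indegree"].sum() == t["weighted_outdegree"].sum() == 7
        assert t.loc["A", "outdegree"] == 2 and t.loc["A", "indegree"] == 1

    def test_self_loop_counts_both_ways(self):
        net = EmotionNetwork("joy", CharacterRoster(("A",)), {("A", "A"): 3.0})
        t = degree_indices(net)
        assert t.loc["A", "weighted_indegree"] == 3
        assert t.loc["A", "weighted_outdegree"] == 3
        assert t.loc["A", "weighted_degree"] == 6

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            net = random_network(rng)
            pd.testing.assert_frame_equal(degree_indices(net), brute_degrees(net))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10**6))
    def test_conservation(self, seed):
        """Total in-weight equals total out-weight equals total edge weight:
        expressed and received emotion balance over the whole network."""
        net = random_network(np.random.default_rng(seed))
        t = degree_indices(net)
        assert t["weighted_indegree"].sum() == pytest.approx(net.total_weight())
        assert t["weighted_outdegree"].sum() == pytest.approx(net.total_weight())
        assert t["weighted_indegree"].mean() == pytest.approx(
            t["weighted_outdegree"].mean()
        )
        assert t["weighted_degree"].mean() == pytest.approx(
            2 * t["weighted_indegree"].mean()
        )

    def test_unweighted_equals_unit_weighted(self):
        net = random_network(np.random.default_rng(5))
        unit = EmotionNetwork(
            net.emotion, net.roster, {e: 1.0 for e in net.edges}
        )
        t, tu = degree_indices(net), degree_indices(unit)
        assert np.array_equal(t["indegree"], tu["weighted_indegree"].astype(int))
        assert np.array_equal(t["outdegree"], tu["weighted_outdegree"].astype(int))

    def test_edge_addition_delta(self):
        roster = CharacterRoster(("A", "B", "C"))
        before = degree_indices(EmotionNetwork("fear", roster, {("A", "B"): 2.0}))
        after = degree_indices(
            EmotionNetwork("fear", roster, {("A", "B"): 2.0, ("C", "A"): 5.0})
        )
        delta = after - before
        assert delta.loc["C", "weighted_outdegree"] == 5
        assert delta.loc["A", "weighted_indegree"] == 5
        assert delta.drop(index=["A", "C"]).to_numpy().sum() == 0


class TestDescriptiveStats:
    def test_worked_example(self):
        table = pd.DataFrame({"weighted_indegree": [1.0, 2.0, 3.0, 4.0]})
        s = descriptive_stats(table)["weighted_indegree"]
        assert s["Mean"] == 2.5
        assert s["Median"] == 2.5
        assert s["Std. Deviation"] == pytest.approx(np.sqrt(5 / 3))  # n-1 denom
        assert s["Std. Error of Mean"] == pytest.approx(np.sqrt(5 / 3) / 2)
        assert s["Maximum"] == 4

    def test_single_node_sd_zero_with_warning(self):
        table = pd.DataFrame({"weighted_indegree": [0.0]})
        with pytest.warns(UserWarning, match="single node"):
            s = descriptive_stats(table)["weighted_indegree"]
        assert s["Std. Deviation"] == 0 and s["Mean"] == 0

    def test_empty_roster_rejected(self):
        with pytest.raises(ValidationError):
            descriptive_stats(pd.DataFrame({"weighted_indegree": []}))


class TestInOutCorrelation:
    def test_identical_vectors(self):
        t = pd.DataFrame(
            {"weighted_indegree": [1.0, 2, 5], "weighted_outdegree": [1.0, 2, 5]}
        )
        assert in_out_correlation(t) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        t = pd.DataFrame(
            {"weighted_indegree": [1.0, 2, 3], "weighted_outdegree": [3.0, 2, 1]}
        )
        assert in_out_correlation(t, "pearson") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.uniform(0, 20, 15), rng.uniform(0, 20, 15)
        t = pd.DataFrame({"weighted_indegree": x, "weighted_outdegree": y})
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert in_out_correlation(t) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_missing(self):
        t = pd.DataFrame(
            {"weighted_indegree": [2.0, 2, 2], "weighted_outdegree": [1.0, 2, 3]}
        )
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(in_out_correlation(t))


class TestTopK:
    def test_ties_broken_by_roster_order(self):
        roster = CharacterRoster(("Zed", "Ann", "Bob"))
        net = EmotionNetwork(
            "fear",
            roster,
            {("Ann", "Zed"): 5.0, ("Bob", "Zed"): 5.0, ("Zed", "Ann"): 1.0},
        )
        t = degree_indices(net)
        top = top_k_table(t, "weighted_outdegree", k=2)
        assert list(top.index) == ["Ann", "Bob"]  # Zed (1.0) excluded; roster order


class TestPersistence:
    @pytest.mark.parametrize("fmt", ["graphml", "gexf"])
    def test_round_trip(self, tmp_path, fmt):
        net = random_network(np.random.default_rng(2), n_nodes=8)
        p = tmp_path / f"net.{fmt}"
        write_network(net, p, metadata={"threshold": 0.15, "seed": 1})
        back = read_network(p)
        assert back.emotion == net.emotion
        assert back.roster.names == net.roster.names
        assert back.edges.keys() == net.edges.keys()
        for k in net.edges:
            assert back.edges[k] == pytest.approx(net.edges[k])

    def test_graphml_embeds_metadata(self, tmp_path):
        import networkx as nx

        net = random_network(np.random.default_rng(3), n_nodes=4)
        p = tmp_path / "net.graphml"
        write_network(net, p, metadata={"threshold": 0.15, "seed": 7})
        g = nx.read_graphml(p)
        assert g.graph["seed"] == 7
        assert g.graph["threshold"] == 0.15
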