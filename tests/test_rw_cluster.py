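"""The Monte-Carlo walk: step weights, penalty, aggregation, selection."""

import itertools

import numpy as np
import pytest

import stagewalk as sw
from stagewalk.rw_cluster import raw_contribution, walk_rng

from conftest import make_stage_network


class ScriptedRNG:
    """Feeds a fixed sequence of neighbor choices to run_walk."""

    def __init__(self, choices):
        self._choices = iter(choices)

    def integers(self, n):
        value = next(self._choices)
        assert 0 <= value < n
        return value


class TestStepWeight:
    @pytest.mark.parametrize(
        "t,expected", [(0, 5.0), (4, 1.0), (2, 3.0)], ids=["start", "end", "middle"]
    )
    def test_linear_decay_from_n_to_one(self, t, expected):
        config = sw.WalkConfig(walk_length_N=5)
        assert sw.step_weight(t, config) == expected

    @pytest.mark.parametrize("t", [-1, 5])
    def test_out_of_range_step_is_a_contract_error(self, t):
        with pytest.raises(sw.ContractError):
            sw.step_weight(t, sw.WalkConfig(walk_length_N=5))


class TestPenaltyCoefficient:
    def test_regular_graph_gives_unit_penalty(self):
        net = make_stage_network([("a", "b"), ("b", "c"), ("c", "a")])
        config = sw.WalkConfig(penalty_exponent_beta=1.7)
        for v in "abc":
            assert sw.penalty_coefficient(v, net, config) == pytest.approx(1.0)

    def test_star_center_penalty_is_degree_over_mean(self):
        net = make_stage_network([("hub", f"leaf{i}") for i in range(4)])
        config = sw.WalkConfig(penalty_exponent_beta=1.0)
        # degrees 4,1,1,1,1 -> mean 1.6; hub penalty 4/1.6
        assert sw.penalty_coefficient("hub", net, config) == pytest.approx(2.5)

    def test_beta_zero_disables_penalty(self):
        net = make_stage_network([("hub", f"leaf{i}") for i in range(4)])
        config = sw.WalkConfig(penalty_exponent_beta=0.0)
        assert sw.penalty_coefficient("hub", net, config) == pytest.approx(1.0)

    def test_isolated_vertex_gets_unit_penalty_and_does_not_shift_mean(self):
        net = make_stage_network([("hub", f"leaf{i}") for i in range(4)], isolates=["x"])
        config = sw.WalkConfig(penalty_exponent_beta=1.0)
        assert sw.penalty_coefficient("x", net, config) == pytest.approx(1.0)
        assert sw.penalty_coefficient("hub", net, config) == pytest.approx(2.5)

    def test_star_center_downweighted_by_exact_degree_ratio_relative_to_leaf(self):
        net = make_stage_network([("hub", f"leaf{i}") for i in range(4)])
        config = sw.WalkConfig(penalty_exponent_beta=1.0)
        ratio = sw.penalty_coefficient("hub", net, config) / sw.penalty_coefficient(
            "leaf0", net, config
        )
        assert ratio == pytest.approx(4.0)


class TestRunWalk:
    def test_single_edge_walk_is_forced(self):
        net = make_stage_network([("a", "b")])
        config = sw.WalkConfig(walk_length_N=3)
        record = sw.run_walk(net, "a", config, ScriptedRNG([0, 0]))
        assert record.visited == [("a", 0), ("b", 1), ("a", 2)]
        assert not record.truncated

    def test_isolated_start_truncates_immediately(self):
        net = make_stage_network([("a", "b")], isolates=["x"])
        config = sw.WalkConfig(walk_length_N=3)
        record = sw.run_walk(net, "x", config, ScriptedRNG([]))
        assert record.visited == [("x", 0)]
        assert record.truncated

    def test_unknown_start_is_a_lookup_error(self):
        net = make_stage_network([("a", "b")])
        with pytest.raises(KeyError):
            sw.run_walk(net, "zz", sw.WalkConfig(), ScriptedRNG([]))

    def test_triangle_walks_enumerate_all_choice_sequences(self):
        """On a triangle with N=4 the walk makes 3 binary choices; the 8
        scripted outcomes are exactly the 8 attainable records, every one a
        valid path in the graph."""
        net = make_stage_network([("a", "b"), ("b", "c"), ("c", "a")])
        config = sw.WalkConfig(walk_length_N=4)
        seen = set()
        for choices in itertools.product([0, 1], repeat=3):
            record = sw.run_walk(net, "a", config, ScriptedRNG(list(choices)))
            assert len(record.visited) == 4 and not record.truncated
            path = tuple(v for v, _ in record.visited)
            for u, v in zip(path, path[1:]):
                assert net.graph.has_edge(u, v)
            seen.add(path)
        assert len(seen) == 8

    def test_seeded_walk_is_reproducible(self):
        net = make_stage_network([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        config = sw.WalkConfig(walk_length_N=10, rng_seed=5)
        r1 = sw.run_walk(net, "a", config, walk_rng(config, "S1", "a", 0))
        r2 = sw.run_walk(net, "a", config, walk_rng(config, "S1", "a", 0))
        assert r1.visited == r2.visited


class TestAccumulateWeights:
    def test_single_edge_forced_walks_give_weight_six(self):
        """a-b with N=3, R=1, beta=0: from a the forced walk a,b,a gives
        a 3+1 and b 2; from b symmetrically; each vertex totals 6."""
        net = make_stage_network([("a", "b")])
        config = sw.WalkConfig(walk_length_N=3, walks_per_vertex_R=1, penalty_exponent_beta=0.0)
        table = sw.accumulate_weights(net, config)
        assert table.weights == {"a": 6.0, "b": 6.0}

    def test_isolate_network_weights_equal_n(self):
        net = make_stage_network([], isolates=["a", "b", "c"])
        config = sw.WalkConfig(walk_length_N=7, walks_per_vertex_R=3)
        table = sw.accumulate_weights(net, config)
        assert all(w == 7.0 for w in table.weights.values())

    def test_every_vertex_appears_with_finite_nonnegative_weight(self, pipeline_result):
        data = pipeline_result["data"]
        config = sw.WalkConfig(walk_length_N=6, walks_per_vertex_R=2, rng_seed=1)
        table = sw.accumulate_weights(data.networks["S1"], config)
        assert set(table.weights) == data.networks["S1"].vertices
        values = np.array(list(table.weights.values()))
        assert np.all(np.isfinite(values)) and np.all(values >= 0)

    def test_determinism_same_config_same_table(self):
        net = make_stage_network([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        config = sw.WalkConfig(walk_length_N=8, walks_per_vertex_R=5, rng_seed=3)
        t1 = sw.accumulate_weights(net, config)
        t2 = sw.accumulate_weights(net, config)
        assert t1.weights == t2.weights

    def test_beta_zero_matches_independent_reimplementation(self):
        """Unpenalized aggregation equals a from-scratch loop that shares only
        the per-walk substream convention."""
        net = make_stage_network([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        config = sw.WalkConfig(
            walk_length_N=6, walks_per_vertex_R=4, penalty_exponent_beta=0.0, rng_seed=11
        )
        expected = {v: 0.0 for v in net.graph}
        n = config.walk_length_N
        adjacency = {v: sorted(net.graph.neighbors(v)) for v in net.graph}
        for start in sorted(net.graph):
            for rep in range(config.walks_per_vertex_R):
                rng = walk_rng(config, "S1", start, rep)
                current = start
                expected[current] += n
                for t in range(1, n):
                    neighbors = adjacency[current]
                    if not neighbors:
                        break
                    current = neighbors[rng.integers(len(neighbors))]
                    expected[current] += n - t
        expected = {v: w / config.walks_per_vertex_R for v, w in expected.items()}
        table = sw.accumulate_weights(net, config)
        assert table.weights == pytest.approx(expected)

    def test_raw_contribution_conserved_for_complete_walks(self):
        """Any non-truncated walk distributes exactly N + (N-1) + ... + 1."""
        rng = np.random.default_rng(0)
        net = make_stage_network([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        config = sw.WalkConfig(walk_length_N=9)
        total = config.walk_length_N * (config.walk_length_N + 1) / 2
        for start in "abcd":
            record = sw.run_walk(net, start, config, rng)
            assert not record.truncated
            assert raw_contribution(record, config) == total

    def test_variance_shrinks_as_replicates_double(self):
        """Monte-Carlo convergence: per-vertex batch variance of the weight
        decreases with R (negative log-log slope)."""
        net = make_stage_network(
            [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"), ("e", "a")]
        )
        r_values = [2, 4, 8, 16]
        mean_vars = []
        for r in r_values:
            batches = []
            for seed in range(8):
                config = sw.WalkConfig(walk_length_N=8, walks_per_vertex_R=r, rng_seed=100 + seed)
                batches.append(sw.accumulate_weights(net, config).weights)
            per_vertex = np.array([[b[v] for v in sorted(net.graph)] for b in batches])
            mean_vars.append(per_vertex.var(axis=0, ddof=1).mean())
        slope = np.polyfit(np.log(r_values), np.log(mean_vars), 1)[0]
        assert slope < 0


class TestSelectVertices:
    def test_outlier_selected_at_default_style_quantile(self):
        table = sw.VertexWeightTable(
            "S1", {"a": 10.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0}, sw.WalkConfig()
        )
        config = sw.WalkConfig(vertex_weight_quantile=0.8)
        assert sw.select_vertices(table, config) == {"a"}

    def test_degenerate_equal_weights_select_nothing(self):
        table = sw.VertexWeightTable("S1", {v: 2.0 for v in "abcd"}, sw.WalkConfig())
        for q in (0.0, 0.5, 0.9):
            assert sw.select_vertices(table, sw.WalkConfig(vertex_weight_quantile=q)) == set()

    def test_quantile_zero_selects_everything_above_minimum(self):
        table = sw.VertexWeightTable("S1", {"a": 1.0, "b": 2.0, "c": 3.0}, sw.WalkConfig())
        config = sw.WalkConfig(vertex_weight_quantile=0.0)
        assert sw.select_vertices(table, config) == {"b", "c"}

    def test_empty_table_is_a_contract_error(self):
        table = sw.VertexWeightTable("S1", {}, sw.WalkConfig())
        with pytest.raises(sw.ContractError):
            sw.select_vertices(table, sw.WalkConfig())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"walk_length_N": 1},
            {"walks_per_vertex_R": 0},
            {"vertex_weight_quantile": 1.0},
            {"vertex_weight_quantile": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(sw.ContractError):
            sw.WalkConfig(**kwargs)
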