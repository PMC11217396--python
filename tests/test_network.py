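"""Linear network composition, fitness, deletion, and waist statistics."""

import numpy as np
import pytest

from bowtie_evo.goals import GoalMatrix, generate_goal
from bowtie_evo.network import (
    LayeredNetwork,
    compose,
    delete_node,
    fitness,
    init_network,
    node_importance,
    waist_stats,
)

DEFINITIONS = ["fitness_drop", "inout_drop", "max_link"]


class TestCompose:
    def test_identity_stack(self):
        net = LayeredNetwork(np.stack([np.eye(3)] * 4))
        np.testing.assert_array_equal(compose(net), np.eye(3))

    def test_single_layer_passthrough(self, rng):
        m = rng.random((1, 4, 4))
        np.testing.assert_array_equal(compose(LayeredNetwork(m)), m[0])

    def test_hand_multiplication(self):
        net = LayeredNetwork(
            np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 1.0], [1.0, 0.0]]])
        )
        np.testing.assert_array_equal(compose(net), [[3.0, 4.0], [1.0, 2.0]])

    def test_bracketing_consistency(self, rng):
        stack = rng.random((5, 4, 4))
        left = compose(stack)
        # alternative bracketing: fold from the other end
        right = stack[-1]
        for l in range(len(stack) - 2, -1, -1):
            right = right @ stack[l]
        np.testing.assert_allclose(left, right, atol=1e-12 * np.abs(left).max())


class TestFitness:
    def test_zero_at_goal(self, rng):
        g = generate_goal(3, 2, 5.0, rng)
        net = LayeredNetwork(np.stack([g.entries, np.eye(3)]))
        assert fitness(net, g) == pytest.approx(0.0, abs=1e-18)

    def test_zero_network_against_norm60_goal(self, rank1_goal):
        net = LayeredNetwork(np.zeros((4, 6, 6)))
        assert fitness(net, rank1_goal) == pytest.approx(-3600.0)

    def test_identity_residual(self):
        net = LayeredNetwork(np.stack([np.eye(2), np.eye(2)]))
        goal = GoalMatrix(np.zeros((2, 2)), rank=0, frob_norm=0.0)
        assert fitness(net, goal) == pytest.approx(-2.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        stack = rng.random((3, 4, 4))
        g = generate_goal(4, 2, 3.0, rng)
        A = compose(stack)
        brute = 0.0
        for i in range(4):
            for j in range(4):
                brute -= (A[i, j] - g.entries[i, j]) ** 2
        assert fitness(stack, g) == pytest.approx(brute, rel=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        net = LayeredNetwork(rng.random((2, 3, 3)))
        with pytest.raises(ValueError):
            fitness(net, np.zeros((4, 4)))


class TestInitNetwork:
    @pytest.mark.parametrize("A0", [0.01, 40.0])
    def test_composed_norm_equals_A0(self, A0, rng):
        net = init_network(6, 4, A0, rng)
        assert np.linalg.norm(compose(net)) == pytest.approx(A0, rel=1e-9)

    def test_entries_strictly_positive(self, rng):
        net = init_network(5, 3, 1.0, rng)
        assert np.all(net.matrices > 0)

    def test_nonpositive_A0_rejected(self, rng):
        with pytest.raises(ValueError):
            init_network(6, 4, 0.0, rng)


class TestDeleteNode:
    def test_zeroes_row_and_column_without_touching_original(self, rng):
        net = init_network(4, 3, 1.0, rng)
        before = net.matrices.copy()
        out = delete_node(net, layer=2, node=1)
        np.testing.assert_array_equal(net.matrices, before)
        assert np.all(out.matrices[0, 1, :] == 0)
        assert np.all(out.matrices[1, :, 1] == 0)

    def test_deleting_dead_node_leaves_fitness_unchanged(self, rng):
        net = init_network(4, 3, 1.0, rng)
        g = generate_goal(4, 1, 2.0, rng)
        dead = delete_node(net, 2, 0)
        assert fitness(delete_node(dead, 2, 0), g) == fitness(dead, g)

    def test_middle_path_hand_computation(self):
        net = LayeredNetwork(np.ones((2, 2, 2)))
        out = delete_node(net, layer=2, node=1)
        np.testing.assert_array_equal(compose(out), np.ones((2, 2)))

    def test_idempotent(self, rng):
        net = init_network(3, 2, 1.0, rng)
        once = delete_node(net, 2, 2)
        twice = delete_node(once, 2, 2)
        np.testing.assert_array_equal(once.matrices, twice.matrices)

    @pytest.mark.parametrize("layer", [1, 4])
    def test_input_output_layers_rejected(self, layer, rng):
        net = init_network(3, 3, 1.0, rng)
        with pytest.raises(ValueError):
            delete_node(net, layer, 0)


class TestNodeImportance:
    @pytest.mark.parametrize("definition", DEFINITIONS)
    def test_symmetric_network_uniform_importance(self, definition, rng):
        net = LayeredNetwork(np.full((4, 6, 6), 0.3))
        g = generate_goal(6, 1, 60.0, rng)
        prof = node_importance(net, g, definition)
        np.testing.assert_allclose(prof.values, 1.0 / 6.0, atol=1e-12)

    @pytest.mark.parametrize("definition", DEFINITIONS)
    def test_rows_sum_to_one(self, definition, rng):
        net = init_network(6, 4, 5.0, rng)
        g = generate_goal(6, 3, 60.0, rng)
        prof = node_importance(net, g, definition)
        np.testing.assert_allclose(prof.values.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_node_scores_zero_under_max_link(self, rng):
        net = init_network(3, 2, 1.0, rng)
        net = delete_node(net, 2, 1)
        g = generate_goal(3, 1, 2.0, rng)
        prof = node_importance(net, g, "max_link")
        assert prof.values[0, 1] == 0.0

    @pytest.mark.parametrize("definition", DEFINITIONS)
    def test_single_carrier_node_takes_all_importance(self, definition, rng):
        # only middle node 0 carries flow; verified by exhaustive deletion
        stack = np.zeros((2, 2, 2))
        stack[0, 0, :] = [1.0, 2.0]
        stack[1, :, 0] = [3.0, 1.0]
        net = LayeredNetwork(stack)
        g = generate_goal(2, 1, 2.0, rng)
        prof = node_importance(net, g, definition)
        assert prof.values[0, 0] == pytest.approx(1.0)
        assert prof.values[0, 1] == pytest.approx(0.0)

    def test_neutral_layer_reports_all_inactive(self):
        # zero network, zero goal: deleting any node changes nothing
        net = LayeredNetwork(np.zeros((2, 2, 2)))
        goal = GoalMatrix(np.zeros((2, 2)), rank=0, frob_norm=0.0)
        prof = node_importance(net, goal, "fitness_drop")
        assert np.all(prof.values == 0.0)
        rep = waist_stats(prof)
        assert rep.waist_size == 0

    def test_unknown_definition_rejected(self, rng):
        net = init_network(3, 2, 1.0, rng)
        g = generate_goal(3, 1, 2.0, rng)
        with pytest.raises(ValueError):
            node_importance(net, g, "degree")


class TestWaistStats:
    def test_uniform_profile_is_not_bowtie(self, rng):
        net = LayeredNetwork(np.full((4, 6, 6), 0.5))
        g = generate_goal(6, 1, 60.0, rng)
        rep = waist_stats(node_importance(net, g))
        assert rep.waist_size == 6
        assert not rep.is_bowtie
        np.testing.assert_array_equal(rep.active_counts, [6, 6, 6])

    def test_single_active_node_is_bowtie_waist_one(self, rng):
        stack = np.zeros((2, 2, 2))
        stack[0, 0, :] = 1.0
        stack[1, :, 0] = 1.0
        rep = waist_stats(
            node_importance(LayeredNetwork(stack), generate_goal(2, 1, 2.0, rng))
        )
        assert rep.waist_size == 1
        assert rep.is_bowtie

    def test_tie_breaks_to_lowest_layer(self):
        from bowtie_evo.network import NodeImportanceProfile

        prof = NodeImportanceProfile(
            values=np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]]),
            definition="fitness_drop",
            threshold=1e-3,
            layers=[2, 3],
        )
        rep = waist_stats(prof)
        assert rep.waist_layer == 2

    def test_default_thresholds_per_definition(self):
        from bowtie_evo.network import DEFAULT_THRESHOLDS

        assert DEFAULT_THRESHOLDS["fitness_drop"] == 1e-3
        assert DEFAULT_THRESHOLDS["inout_drop"] == 1e-3
        assert DEFAULT_THRESHOLDS["max_link"] == 0.05

    def test_nonpositive_threshold_rejected(self, rng):
        net = init_network(3, 2, 1.0, rng)
        prof = node_importance(net, generate_goal(3, 1, 2.0, rng))
        with pytest.raises(ValueError):
            waist_stats(prof, threshold=0.0)


def test_network_json_roundtrip(tmp_path, rng):
    net = init_network(4, 3, 2.0, rng)
    net.save(tmp_path / "net.json")
    back = LayeredNetwork.load(tmp_path / "net.json")
    np.testing.assert_array_equal(back.matrices, net.matrices)
    assert (back.M, back.L) == (4, 3)


def test_negative_entries_rejected():
    with pytest.raises(ValueError):
        LayeredNetwork(-np.ones((2, 2, 2)))
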