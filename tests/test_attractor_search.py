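"""Branch-and-propagate fixed-point enumeration: rules, heuristic, search, oracle."""

import numpy as np
import pytest

from sibnet import (
    ResourceLimitError,
    SignedNetwork,
    brute_force_singleton_attractors,
    decompose,
    enumerate_singleton_attractors,
    format_partial,
    inhibitory_degree,
    parse_partial,
    propagate,
    select_branch_node,
)
from sibnet.network_model import UNKNOWN, is_singleton_attractor

from conftest import YEAST_ATTRACTORS, random_networks


class TestInhibitoryDegree:
    def test_zero_when_no_inhibitory_edges(self):
        net = SignedNetwork(a=np.array([[0, 1], [1, 0]]))
        dec = decompose(net)
        assert [inhibitory_degree(dec, i) for i in (1, 2)] == [0, 0]

    def test_mutual_inhibition_in_plus_out(self, mutual_inhibition):
        dec = decompose(mutual_inhibition)
        assert [inhibitory_degree(dec, i) for i in (1, 2)] == [2, 2]

    def test_self_inhibition_counted_in_both_sums(self):
        dec = decompose(SignedNetwork(a=np.array([[-1]])))
        assert inhibitory_degree(dec, 1) == 2

    def test_yeast_degrees_rank_main_cyclins_first(self, yeast_dec):
        degrees = [inhibitory_degree(yeast_dec, i) for i in range(1, 12)]
        assert degrees == [2, 1, 1, 4, 4, 3, 4, 4, 5, 8, 2]
        order = sorted(range(1, 12), key=lambda i: (-degrees[i - 1], i))
        # the search branches on Clb1/2 (node 10) first, then Sic1 (node 9),
        # exactly as in the worked flow chart
        assert order[:2] == [10, 9]

    def test_index_out_of_range(self, yeast_dec):
        with pytest.raises(IndexError):
            inhibitory_degree(yeast_dec, 12)


class TestSelectBranchNode:
    def test_yeast_first_branch_is_node_10(self, yeast_dec):
        assert select_branch_node(yeast_dec, "0" + "?" * 10) == 10

    def test_tie_break_by_smallest_index(self, empty_net):
        dec = decompose(empty_net(5))
        assert select_branch_node(dec, "1?00?") == 2

    def test_single_unknown_returned(self, yeast_dec):
        assert select_branch_node(yeast_dec, "00110?00000") == 6

    def test_no_unknown_raises(self, yeast_dec):
        with pytest.raises(ValueError):
            select_branch_node(yeast_dec, "00110000000")


class TestPropagate:
    def test_yeast_fully_unknown_pins_only_node_1(self, yeast_dec):
        out = propagate(yeast_dec, "?" * 11, trace=True)
        assert out.status == "consistent"
        assert format_partial(out.state) == "0??????????"
        assert ("5", 1) in out.fired_rules

    def test_yeast_node10_on_contradicts(self, yeast_dec):
        out = propagate(yeast_dec, "0????????1?")
        assert out.is_contradiction

    def test_yeast_sic1_on_leaves_nodes_2_and_5(self, yeast_dec):
        out = propagate(yeast_dec, "0???????1?0"[:9] + "0?")
        assert format_partial(out.state) == "0?00?000100"

    def test_empty_network_is_inert(self, empty_net):
        dec = decompose(empty_net(4))
        out = propagate(dec, "?1?0")
        assert out.status == "consistent"
        assert format_partial(out.state) == "?1?0"
        assert out.fired_rules == ()

    def test_determined_entries_never_flip(self):
        """Propagation only ever extends a partial state (monotone, no flips)."""
        for net, rng in random_networks(seed=11, count=60):
            dec = decompose(net)
            partial = rng.choice([0, 1, UNKNOWN], size=net.n_nodes).astype(np.int8)
            out = propagate(dec, partial)
            if out.status == "consistent":
                was_set = partial != UNKNOWN
                assert np.array_equal(out.state[was_set], partial[was_set])
                assert np.count_nonzero(out.state == UNKNOWN) <= np.count_nonzero(
                    partial == UNKNOWN
                )

    def test_determinations_are_entailed(self):
        """Whatever propagation pins down holds in every fixed-point completion."""
        checked = 0
        for net, rng in random_networks(seed=12, count=40, n_range=(3, 8)):
            dec = decompose(net)
            partial = rng.choice(
                [0, 1, UNKNOWN], size=net.n_nodes, p=[0.25, 0.25, 0.5]
            ).astype(np.int8)
            out = propagate(dec, partial)
            completions = [
                np.array([(x >> (net.n_nodes - 1 - k)) & 1 for k in range(net.n_nodes)])
                for x in range(1 << net.n_nodes)
            ]
            fixed = [
                s
                for s in completions
                if is_singleton_attractor(dec, s)
                and np.all((partial == UNKNOWN) | (s == partial))
            ]
            if out.is_contradiction:
                assert fixed == []
            else:
                for s in fixed:
                    det = out.state != UNKNOWN
                    assert np.array_equal(s[det], out.state[det])
                    checked += 1
        assert checked > 10  # the scenario actually exercised the claim


class TestEnumerate:
    def test_yeast_seven_attractors_exact(self, yeast):
        found, stats = enumerate_singleton_attractors(yeast)
        assert found == YEAST_ATTRACTORS
        assert stats.attractors_found == 7
        assert not stats.capped

    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_edgeless_network_has_all_states_fixed(self, empty_net, n):
        found, _ = enumerate_singleton_attractors(empty_net(n))
        assert len(found) == 1 << n

    def test_mutual_inhibition(self, mutual_inhibition):
        found, _ = enumerate_singleton_attractors(mutual_inhibition)
        assert found == {"00", "10", "01"}

    @pytest.mark.parametrize(
        "a, expected", [([[-1]], {"0"}), ([[1]], {"1"}), ([[0]], {"0", "1"})]
    )
    def test_one_node_networks(self, a, expected):
        found, _ = enumerate_singleton_attractors(SignedNetwork(a=np.array(a)))
        assert found == expected

    def test_result_cap_flags_truncation(self, empty_net):
        found, stats = enumerate_singleton_attractors(empty_net(6), max_attractors=10)
        assert len(found) == 10
        assert stats.capped

    def test_stats_counters_consistent(self, yeast):
        _, stats = enumerate_singleton_attractors(yeast)
        assert stats.nodes_expanded > 0
        assert stats.propagation_passes > 0
        assert stats.contradictions >= 1


class TestBruteForce:
    def test_yeast_agrees_with_rule_based_search(self, yeast):
        assert brute_force_singleton_attractors(yeast) == YEAST_ATTRACTORS

    @pytest.mark.parametrize("a, expected", [([[-1]], {"0"}), ([[1]], {"1"})])
    def test_one_node_networks(self, a, expected):
        assert brute_force_singleton_attractors(SignedNetwork(a=np.array(a))) == expected

    def test_ceiling_refused(self, empty_net):
        with pytest.raises(ResourceLimitError, match="ceiling"):
            brute_force_singleton_attractors(empty_net(30))


def test_oracle_equivalence_on_random_ensembles():
    """The rule-based enumeration returns exactly the exhaustive-scan fixed
    points: same set, no duplicates, no misses (duplicates are impossible by
    construction since branches partition the completions)."""
    for net, _ in random_networks(seed=2024, count=60):
        found, _ = enumerate_singleton_attractors(net)
        assert found == brute_force_singleton_attractors(net)
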