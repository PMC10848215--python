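import numpy as np
import pytest

from edgeprior import (
    GeneratorSpec,
    Network,
    PermutationConfig,
    degree_sequence,
    generate_network,
    is_valid_swap,
    permute,
    permute_heterogeneous,
    retained_fraction_curve,
)
from edgeprior.synthetic import enumerate_degree_matching_graphs


class TestIsValidSwap:
    def test_generic_valid_swap(self):
        net = Network.from_edges([(0, 1), (2, 3)], n_source=4)
        ok, reason = is_valid_swap((0, 1), (2, 3), net)
        assert ok and reason is None

    def test_swap_recreating_existing_edge_rejected(self):
        # (a,b),(c,b) with shared target: new edge (c,b) duplicates (c,b)
        net = Network.from_edges([(0, 1), (2, 1)], n_source=3)
        ok, reason = is_valid_swap((0, 1), (2, 1), net)
        assert not ok and reason == "existing_edge"

    def test_antiparallel_pair_forces_loops(self):
        net = Network.from_edges([(0, 1), (1, 0)], n_source=2, directed=True)
        ok, reason = is_valid_swap((0, 1), (1, 0), net)
        assert not ok and reason == "loop"

    def test_loop_allowed_when_flagged(self):
        net = Network.from_edges([(0, 1), (1, 0)], n_source=2, directed=True)
        ok, reason = is_valid_swap(
            (0, 1), (1, 0), net, PermutationConfig(allow_loops=True)
        )
        assert ok

    def test_antiparallel_creation_rejected(self):
        net = Network.from_edges([(0, 1), (2, 0), (3, 2)], n_source=4, directed=True)
        # swap (0,1),(3,2) -> (0,2),(3,1); (0,2) is antiparallel to existing (2,0)
        ok, reason = is_valid_swap((0, 1), (3, 2), net)
        assert not ok and reason == "antiparallel"
        ok, _ = is_valid_swap(
            (0, 1), (3, 2), net, PermutationConfig(allow_antiparallel=True)
        )
        assert ok

    def test_excluded_pair_rejected(self):
        net = Network.from_edges([(0, 1), (2, 3)], n_source=4)
        cfg = PermutationConfig(excluded_pairs=frozenset({(0, 3)}))
        ok, reason = is_valid_swap((0, 1), (2, 3), net, cfg)
        assert not ok and reason == "excluded"

    def test_same_edge_rejected(self):
        net = Network.from_edges([(0, 1), (2, 3)], n_source=4)
        ok, reason = is_valid_swap((0, 1), (0, 1), net)
        assert not ok and reason == "same_edge_pair"

    def test_nonexistent_edge_raises(self):
        net = Network.from_edges([(0, 1), (2, 3)], n_source=4)
        with pytest.raises(ValueError, match="must exist"):
            is_valid_swap((0, 2), (2, 3), net)


class TestPermute:
    def test_triangle_is_unique_realization(self, triangle):
        permuted, stats = permute(triangle, PermutationConfig(swap_attempts=1000, seed=0))
        assert permuted.edges == triangle.edges
        assert stats.retained_fraction == 1.0
        assert stats.performed == 0

    def test_path_is_unique_realization(self, path3):
        permuted, _ = permute(path3, PermutationConfig(swap_attempts=500, seed=1))
        assert permuted.edges == path3.edges

    def test_four_cycle_reaches_all_two_regular_graphs(self, four_cycle):
        reachable, _ = enumerate_degree_matching_graphs(four_cycle)
        assert len(reachable) == 3
        seen = set()
        for seed in range(3):
            permuted, _ = permute(four_cycle, PermutationConfig(multiplier=10, seed=seed))
            deg = degree_sequence(permuted)
            assert (deg.source == 2).all()
            assert permuted.edges in reachable
            seen.add(permuted.edges)

    @pytest.mark.parametrize(
        "fixture", ["sparse_config_model", "bipartite_net", "directed_net"]
    )
    def test_degree_and_edge_count_preserved(self, fixture, request):
        net = request.getfixturevalue(fixture)
        orig = degree_sequence(net)
        for seed in range(3):
            permuted, stats = permute(net, PermutationConfig(seed=seed))
            new = degree_sequence(permuted)
            assert permuted.m == net.m
            assert np.array_equal(orig.source, new.source)
            assert np.array_equal(orig.target, new.target)
            stats.check()

    def test_no_loops_or_antiparallel_created(self, directed_net):
        permuted, _ = permute(directed_net, PermutationConfig(seed=9))
        for i, j in permuted.edges:
            assert i != j
            assert (j, i) not in permuted.edges

    def test_input_network_unmodified(self, four_cycle):
        before = set(four_cycle.edges)
        permute(four_cycle, PermutationConfig(seed=2))
        assert set(four_cycle.edges) == before

    def test_deterministic_given_seed(self, sparse_config_model):
        cfg = PermutationConfig(seed=123)
        p1, s1 = permute(sparse_config_model, cfg)
        p2, s2 = permute(sparse_config_model, cfg)
        assert p1.edges == p2.edges
        assert s1.to_dict() == s2.to_dict()

    def test_single_edge_warns_and_returns_copy(self):
        net = Network.from_edges([(0, 1)], n_source=2)
        with pytest.warns(UserWarning, match="fewer than 2 edges"):
            permuted, stats = permute(net, PermutationConfig(swap_attempts=10))
        assert permuted.edges == net.edges
        assert stats.attempts == 0

    def test_excluded_pair_never_exists_after_permutation(self, sparse_config_model):
        # exclude one original edge and one non-edge: neither may exist afterwards
        edge = sorted(sparse_config_model.edges)[0]
        non_edge = next(
            (i, j)
            for i in range(sparse_config_model.n_source)
            for j in range(i + 1, sparse_config_model.n_source)
            if not sparse_config_model.has_edge(i, j)
        )
        cfg = PermutationConfig(
            excluded_pairs=frozenset({edge, non_edge}), multiplier=30, seed=0
        )
        permuted, stats = permute(sparse_config_model, cfg)
        assert edge not in permuted.edges
        assert non_edge not in permuted.edges

    def test_stats_accounting_balances(self, sparse_config_model):
        _, stats = permute(sparse_config_model, PermutationConfig(seed=3))
        assert stats.attempts == stats.performed + (
            stats.rejected_same_edge_pair
            + stats.rejected_loop
            + stats.rejected_antiparallel
            + stats.rejected_existing_edge
            + stats.rejected_excluded
        )


class TestHeterogeneous:
    def test_per_type_degrees_preserved_independently(self, sparse_config_model, directed_net):
        nets = {"ppi": sparse_config_model, "regulates": directed_net}
        results = permute_heterogeneous(nets, PermutationConfig(seed=0))
        for key, net in nets.items():
            permuted, _ = results[key]
            orig, new = degree_sequence(net), degree_sequence(permuted)
            assert np.array_equal(orig.source, new.source)
            assert np.array_equal(orig.target, new.target)

    def test_single_type_matches_permute(self, sparse_config_model):
        cfg = PermutationConfig(seed=7)
        solo, _ = permute(sparse_config_model, cfg)
        hetero, _ = permute_heterogeneous({"only": sparse_config_model}, cfg)["only"]
        assert solo.edges == hetero.edges

    def test_tiny_type_returned_unchanged(self, sparse_config_model):
        tiny = Network.from_edges([(0, 1)], n_source=2)
        with pytest.warns(UserWarning):
            results = permute_heterogeneous(
                {"tiny": tiny, "big": sparse_config_model}, PermutationConfig(seed=0)
            )
        assert results["tiny"][0].edges == tiny.edges
        assert results["big"][1].performed > 0


class TestRetainedFractionCurve:
    def test_zero_multiplier_retains_everything(self, sparse_config_model):
        curve = retained_fraction_curve(sparse_config_model, [0.0], seed=0)
        assert curve["retained_fraction"].iloc[0] == 1.0

    def test_triangle_always_fully_retained(self, triangle):
        curve = retained_fraction_curve(triangle, [1, 10, 100], seed=0)
        assert (curve["retained_fraction"] == 1.0).all()

    def test_curve_flattens_to_asymptote(self):
        """Sparse 500-node/~1000-edge graph: retention at 20m ~ retention at 10m."""
        net = generate_network(
            GeneratorSpec(kind="configuration_model", n_nodes=500, exponent=2.1, min_degree=2, seed=21)
        )
        diffs = []
        for seed in range(10):
            curve = retained_fraction_curve(net, [10, 20], seed=seed)
            diffs.append(
                curve["retained_fraction"].iloc[1] - curve["retained_fraction"].iloc[0]
            )
        assert abs(np.mean(diffs)) < 0.02
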