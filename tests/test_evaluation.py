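import numpy as np
import pytest

from edgeprior import (
    Network,
    auroc,
    brier_decomposition,
    calibration_curve,
    permuted_feature_baseline,
    run_task,
    sample_holdout,
)
from conftest import brute_force_auroc


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_scores_all_ties(self):
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_half_ordered(self):
        assert auroc([0.9, 0.2, 0.8, 0.1], [1, 0, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 2])

    def test_matches_brute_force_with_heavy_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=300)
            labels = rng.random(300) < scores
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-10
            )


class TestCalibration:
    def test_degenerate_groups(self):
        res = calibration_curve([1.0, 1.0], [1, 1])
        assert len(res.groups) == 1
        assert res.groups.observed.iloc[0] == 1.0
        res2 = calibration_curve([0.5] * 4, [1, 0, 1, 0])
        assert res2.groups.observed.iloc[0] == 0.5

    def test_bernoulli_draws_are_calibrated(self):
        """Labels ~ Bernoulli(score): observed tracks predicted per decile."""
        rng = np.random.default_rng(1)
        scores = rng.choice(np.linspace(0.05, 0.95, 10), size=100_000)
        labels = rng.random(scores.size) < scores
        res = calibration_curve(scores, labels)
        assert np.abs(res.groups.mean_score - res.groups.observed).max() < 0.02

    def test_quantile_binning(self):
        rng = np.random.default_rng(2)
        scores = rng.random(1000)
        labels = rng.random(1000) < scores
        res = calibration_curve(scores, labels, grouping="quantile")
        assert len(res.groups) <= 20
        assert res.groups["size"].sum() == 1000


class TestBrierDecomposition:
    def test_perfect_predictions(self):
        res = brier_decomposition([0.0, 1.0, 1.0], [0, 1, 1])
        assert res.brier == res.calibration == res.refinement == 0.0

    def test_constant_base_rate_score(self):
        # constant score p equal to the base rate: calibration 0, refinement p(1-p)
        res = brier_decomposition([0.25] * 8, [1, 0, 0, 0] * 2)
        assert res.calibration == pytest.approx(0.0, abs=1e-12)
        assert res.refinement == pytest.approx(0.25 * 0.75)

    def test_overconfident_constant_score(self):
        res = brier_decomposition([1.0] * 4, [1, 0, 1, 0])
        assert res.brier == pytest.approx(0.5)
        assert res.calibration == pytest.approx(0.25)
        assert res.refinement == pytest.approx(0.25)

    def test_identity_holds_on_random_data(self):
        rng = np.random.default_rng(3)
        scores = rng.choice(np.linspace(0, 1, 7), size=5000)
        labels = rng.random(5000) < scores
        res = brier_decomposition(scores, labels)
        assert res.brier == pytest.approx(res.calibration + res.refinement, abs=1e-10)


class TestSampleHoldout:
    def test_counts_and_partition(self):
        net = Network.from_edges([(i, i + 1) for i in range(10)])
        sampled, heldout = sample_holdout(net, 0.7, seed=0)
        assert sampled.m == 7
        assert len(heldout) == 3
        assert sampled.edges | heldout == net.edges
        assert not (sampled.edges & heldout)

    def test_deterministic(self, sparse_config_model):
        s1, h1 = sample_holdout(sparse_config_model, 0.7, seed=5)
        s2, h2 = sample_holdout(sparse_config_model, 0.7, seed=5)
        assert s1.edges == s2.edges and h1 == h2

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1])
    def test_invalid_fraction(self, sparse_config_model, fraction):
        with pytest.raises(ValueError):
            sample_holdout(sparse_config_model, fraction)

    def test_degenerate_sample_rejected(self):
        net = Network.from_edges([(0, 1), (1, 2)])
        with pytest.raises(ValueError, match="empty or complete"):
            sample_holdout(net, 0.01)


class TestRunTask:
    def test_complete_graph_has_no_negatives(self, k4):
        with pytest.raises(ValueError, match="single class"):
            run_task(1, k4, predictors=["degree_product"], n_permutations=2)

    def test_four_cycle_prior_is_all_ties(self, four_cycle):
        res = run_task(1, four_cycle, predictors=["prior"], n_permutations=200, seed=0)
        assert res.auroc.iloc[0] == 0.5  # all 6 pairs share the grouped prior 2/3

    def test_task2_excludes_sampled_edges(self, sparse_config_model):
        res = run_task(
            2, sparse_config_model, predictors=["degree_product"],
            holdout_fraction=0.7, seed=1,
        )
        n_total = sparse_config_model.n_source * (sparse_config_model.n_source - 1) // 2
        sampled_m = int(round(0.7 * sparse_config_model.m))
        assert res.n_pairs.iloc[0] == n_total - sampled_m
        assert res.n_positive.iloc[0] == sparse_config_model.m - sampled_m

    def test_task3_on_permuted_twin_matches_task1(self, sparse_config_model):
        """A degree-preserving permutation shares its degree sequence, so the
        prior performs comparably predicting it and the original."""
        from edgeprior import PermutationConfig, permute

        twin, _ = permute(sparse_config_model, PermutationConfig(seed=77))
        r1 = run_task(1, sparse_config_model, predictors=["prior"], n_permutations=50, seed=2)
        r3 = run_task(
            3, sparse_config_model, second=twin, predictors=["prior"],
            n_permutations=50, seed=2,
        )
        assert abs(r1.auroc.iloc[0] - r3.auroc.iloc[0]) <= 0.05

    def test_task3_requires_shared_node_space(self, sparse_config_model):
        other = Network.from_edges([(0, 1)], n_source=2)
        with pytest.raises(ValueError, match="node index spaces"):
            run_task(3, sparse_config_model, second=other, predictors=["prior"])

    def test_results_are_tidy(self, sparse_config_model):
        res = run_task(
            1, sparse_config_model,
            predictors=["prior", "approximation", "degree_product"],
            n_permutations=20, seed=3,
        )
        assert list(res.columns) == [
            "task", "predictor", "auroc", "brier", "calibration",
            "refinement", "n_pairs", "n_positive",
        ]
        assert len(res) == 3
        assert res.brier.notna().all()


class TestPermutedFeatureBaseline:
    def test_degree_only_feature_invariant_under_permutation(self, sparse_config_model):
        from edgeprior import feature_matrix
        from edgeprior.prior import admissible_pairs

        src, tgt = admissible_pairs(sparse_config_model)
        labels = np.array(
            [sparse_config_model.has_edge(i, j) for i, j in zip(src, tgt)]
        )
        unpermuted = auroc(
            feature_matrix(sparse_config_model, "preferential_attachment")[src, tgt],
            labels,
        )
        baseline = permuted_feature_baseline(
            sparse_config_model, "preferential_attachment", 10, seed=4
        )
        assert np.allclose(baseline, unpermuted, atol=1e-12)

    def test_structure_feature_degrades_under_permutation(self):
        from edgeprior import GeneratorSpec, generate_network, feature_matrix
        from edgeprior.prior import admissible_pairs

        net = generate_network(
            GeneratorSpec(kind="planted_partition", n_nodes=120, n_blocks=4,
                          p_in=0.25, p_out=0.01, seed=8)
        )
        src, tgt = admissible_pairs(net)
        labels = np.array([net.has_edge(i, j) for i, j in zip(src, tgt)])
        unpermuted = auroc(feature_matrix(net, "jaccard")[src, tgt], labels)
        baseline = permuted_feature_baseline(net, "jaccard", 20, seed=9)
        assert baseline.mean() < unpermuted
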