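"""Defer loss oracle checks and defer-network training behavior."""

import math

import numpy as np
import pytest

import ldu
from ldu.defer import DEFER, DeferModelSpec, DeferNetwork, defer_loss, triage


# -- independent cross-entropy oracle ---------------------------------------

def brute_cross_entropy(scores, j):
    scores = list(scores)
    denom = sum(math.exp(s) for s in scores)
    return -math.log(math.exp(scores[j]) / denom)


class TestDeferLoss:
    def test_matches_weighted_cross_entropy_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            scores = rng.normal(scale=3.0, size=3)
            target = int(rng.integers(2))
            alpha = float(rng.uniform(0.05, 5.0))
            expected = alpha * brute_cross_entropy(scores, target) + brute_cross_entropy(
                scores, 2
            )
            assert defer_loss(scores, target, alpha) == pytest.approx(
                expected, abs=1e-10
            )

    @pytest.mark.parametrize(
        "target, alpha, expected",
        [
            (0, 1.0, 2 * math.log(3.0)),  # 2.197225
            (1, 2.0, 3 * math.log(3.0)),  # 3.295837
        ],
    )
    def test_uniform_score_reference_values(self, target, alpha, expected):
        assert defer_loss(np.zeros(3), target, alpha) == pytest.approx(
            expected, abs=1e-9
        )

    def test_alpha_placements_coincide_at_alpha_one(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            scores = rng.normal(size=3)
            target = int(rng.integers(2))
            assert defer_loss(scores, target, 1.0, alpha_on="target") == defer_loss(
                scores, target, 1.0, alpha_on="defer"
            )

    def test_large_alpha_is_dominated_by_the_target_term(self):
        scores = np.array([1.0, -0.5, 0.3])
        ce_target = brute_cross_entropy(scores, 0)
        for alpha in (1e3, 1e6):
            assert defer_loss(scores, 0, alpha) / alpha == pytest.approx(
                ce_target, rel=1e-2 / alpha * 1e3
            )

    @pytest.mark.parametrize(
        "scores, target, alpha",
        [
            (np.zeros(3), 0, 0.0),
            (np.zeros(3), 0, -1.0),
            (np.array([1.0, np.inf, 0.0]), 0, 1.0),
            (np.zeros(3), 2, 1.0),  # defer is not a valid target
            (np.zeros(4), 0, 1.0),
        ],
    )
    def test_invalid_inputs_raise(self, scores, target, alpha):
        with pytest.raises(ValueError):
            defer_loss(scores, target, alpha)


class TestTriageDecisionRule:
    def _model_returning(self, logits):
        net = DeferNetwork(3, DeferModelSpec(alpha=1.0, seed=0))
        net.decision_scores = lambda X: np.atleast_2d(np.asarray(logits, dtype=float))
        return net

    @pytest.mark.parametrize(
        "softmax_probs, deferred, pred",
        [
            ((0.2, 0.3, 0.5), True, DEFER),  # defer is argmax
            ((0.7, 0.1, 0.2), False, 0),
            ((0.1, 0.6, 0.3), False, 1),
            ((0.4, 0.2, 0.4), True, DEFER),  # class-0/defer tie -> defer
            ((0.3, 0.3, 0.4), True, DEFER),
        ],
    )
    def test_argmax_with_ties_to_defer(self, softmax_probs, deferred, pred):
        logits = np.log(np.asarray(softmax_probs))
        result = triage(self._model_returning(logits), np.zeros((1, 3)))
        assert bool(result.deferred[0]) is deferred
        assert result.pred[0] == pred

    def test_class_tie_breaks_positive(self):
        result = triage(
            self._model_returning(np.log([0.4, 0.4, 0.2])), np.zeros((1, 3))
        )
        assert not result.deferred[0] and result.pred[0] == 1


class TestTrainDeferNetwork:
    def test_tiny_alpha_defers_almost_everything(self, mixed_cohort, stage2_features):
        train, _ = mixed_cohort
        features_train, features_test = stage2_features
        net = ldu.train_defer_network(
            features_train, train.label, DeferModelSpec(alpha=0.01, seed=1)
        )
        result = triage(net, features_train)
        assert result.defer_rate >= 0.99

    def test_huge_alpha_defers_almost_nothing(self, mixed_cohort, stage2_features):
        train, _ = mixed_cohort
        features_train, _ = stage2_features
        net = ldu.train_defer_network(
            features_train, train.label, DeferModelSpec(alpha=100.0, seed=1)
        )
        assert triage(net, features_train).defer_rate <= 0.01

    def test_training_is_deterministic_per_seed(self, mixed_cohort, stage2_features):
        train, _ = mixed_cohort
        features_train, features_test = stage2_features
        spec = DeferModelSpec(alpha=1.3, seed=9)
        a = ldu.train_defer_network(features_train, train.label, spec)
        b = ldu.train_defer_network(features_train, train.label, spec)
        np.testing.assert_array_equal(
            a.decision_scores(features_test), b.decision_scores(features_test)
        )

    def test_deferred_set_is_enriched_for_hard_subgroups(
        self, mixed_cohort, stage2_features
    ):
        """At an intermediate alpha the deferred set concentrates on the
        ambiguous and mislabeled-confident subgroups, not the easy one."""
        train, test = mixed_cohort
        features_train, features_test = stage2_features
        net = ldu.train_defer_network(
            features_train, train.label, DeferModelSpec(alpha=1.5, seed=2)
        )
        result = triage(net, features_test)
        hard = np.isin(test.subgroup, ("ambiguous", "overconfident_wrong"))
        hard_rate = result.deferred[hard].mean()
        easy_rate = result.deferred[~hard].mean()
        ratio = math.inf if easy_rate == 0 else hard_rate / easy_rate
        assert ratio > 2

    def test_width_mismatch_raises(self, mixed_cohort, stage2_features):
        train, _ = mixed_cohort
        features_train, _ = stage2_features
        net = ldu.train_defer_network(
            features_train, train.label, DeferModelSpec(alpha=1.0, seed=0)
        )
        with pytest.raises(ValueError, match="width"):
            net.decision_scores(features_train[:, :-1])

    def test_single_class_labels_raise(self):
        features = np.random.default_rng(0).uniform(size=(10, 4))
        with pytest.raises(ValueError, match="class"):
            ldu.train_defer_network(
                features, np.zeros(10, dtype=int), DeferModelSpec(alpha=1.0)
            )


def test_spec_validation():
    with pytest.raises(ValueError, match="alpha"):
        DeferModelSpec(alpha=0.0)
    with pytest.raises(ValueError, match="alpha_on"):
        DeferModelSpec(alpha=1.0, alpha_on="both")
    assert DeferModelSpec(alpha=1.0).output_size == 3


def test_save_load_roundtrip(tmp_path, mixed_cohort, stage2_features):
    train, _ = mixed_cohort
    features_train, features_test = stage2_features
    net = ldu.train_defer_network(
        features_train, train.label, DeferModelSpec(alpha=1.2, seed=4)
    )
    ldu.defer.save_defer_network(net, tmp_path / "net")
    back = ldu.defer.load_defer_network(tmp_path / "net")
    np.testing.assert_array_equal(
        net.decision_scores(features_test), back.decision_scores(features_test)
    )
    assert back.spec == net.spec


def test_train_ldu_pipeline_end_to_end(mixed_cohort, fast_base_spec):
    train, test = mixed_cohort
    pipeline = ldu.train_ldu(
        train, fast_base_spec, K=3, defer_spec=DeferModelSpec(alpha=1.3, seed=0),
        master_seed=2,
    )
    result = ldu.triage_ldu(pipeline, test)
    assert len(result) == len(test)
    assert result.algorithm == "LDU"
    # scores behave like probabilities
    np.testing.assert_allclose(result.scores.sum(axis=1), 1.0, atol=1e-9)
    # exactly one of {class, defer} per sample
    assert np.all((result.pred == DEFER) == result.deferred)
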