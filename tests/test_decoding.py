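"""Pseudo-population assembly and SVM decoding pipelines."""

import numpy as np
import pytest

from numprod import (
    BehaviorParams,
    DecodingSpec,
    PopulationSpec,
    build_pseudopopulation,
    cv_accuracy,
    decode_numbers,
    error_generalization,
    generate_session,
    n_binary_problems,
    outcome_classifier,
    svm_crossval,
)
from numprod.decoding import _zscore_pair, cross_protocol_decode


def _noise_unit_rates(n_units, classes, trials, rng, scale=1.0, signal=0.0):
    """Per-unit class pools: optional linear class signal plus noise."""
    return {
        f"u{i}": {
            c: signal * ci + scale * rng.normal(size=trials)
            for ci, c in enumerate(classes)
        }
        for i in range(n_units)
    }


def test_one_vs_one_decomposition_counts():
    assert n_binary_problems(5) == 10
    assert n_binary_problems(3) == 3
    assert n_binary_problems(2) == 1


class TestPseudopopulation:
    def test_shape_two_units_two_classes(self):
        rng = np.random.default_rng(0)
        ur = _noise_unit_rates(2, ["a", "b"], 25, rng)
        X, y = build_pseudopopulation(ur, ["a", "b"], 20, rng)
        assert X.shape == (40, 2)
        assert np.bincount(y).tolist() == [20, 20]

    def test_fixed_seed_gives_identical_draw(self):
        ur = _noise_unit_rates(3, [1, 2], 30, np.random.default_rng(5))
        X1, _ = build_pseudopopulation(ur, [1, 2], 10, np.random.default_rng(42))
        X2, _ = build_pseudopopulation(ur, [1, 2], 10, np.random.default_rng(42))
        np.testing.assert_array_equal(X1, X2)

    def test_draws_are_without_replacement(self):
        ur = {"u0": {0: np.arange(20.0), 1: np.arange(20.0, 40.0)}}
        X, _ = build_pseudopopulation(ur, [0, 1], 20, np.random.default_rng(0))
        assert len(set(X[:20, 0])) == 20


class TestZScoring:
    def test_test_fold_uses_training_parameters(self):
        # regression guard: the test set must be standardized with the
        # training-fold mean/SD, never its own
        rng = np.random.default_rng(0)
        train = rng.normal(5.0, 2.0, size=(30, 3))
        test = rng.normal(50.0, 20.0, size=(10, 3))
        ztr, zte = _zscore_pair(train, test)
        mu, sd = train.mean(0), train.std(0)
        np.testing.assert_allclose(zte, (test - mu) / sd)
        assert np.abs(zte.mean()) > 1.0  # far off-center: its own stats were NOT used
        np.testing.assert_allclose(ztr.mean(0), 0.0, atol=1e-12)

    def test_zero_variance_feature_zeroed(self):
        train = np.ones((10, 2))
        train[:, 1] = np.arange(10)
        test = np.full((4, 2), 7.0)
        ztr, zte = _zscore_pair(train, test)
        assert not np.isnan(zte).any()
        assert (zte[:, 0] == 0).all()


class TestCrossValidation:
    def test_separable_features_decode_perfectly(self):
        rng = np.random.default_rng(1)
        ur = _noise_unit_rates(4, [1, 2, 3, 4, 5], 30, rng, scale=0.01, signal=1.0)
        spec = DecodingSpec(resamples=5, shuffle_resamples=5, seed=0)
        res = svm_crossval(ur, [1, 2, 3, 4, 5], spec)
        assert res.mean_accuracy == pytest.approx(1.0)
        np.testing.assert_allclose(res.confusion, np.eye(5), atol=1e-12)

    def test_noise_features_decode_at_chance(self):
        rng = np.random.default_rng(2)
        ur = _noise_unit_rates(6, [1, 2, 3, 4, 5], 30, rng)
        spec = DecodingSpec(resamples=20, shuffle_resamples=20, seed=0)
        res = svm_crossval(ur, [1, 2, 3, 4, 5], spec)
        assert abs(res.mean_accuracy - 0.2) < 0.06
        assert res.null_percentile(5) <= res.mean_accuracy <= res.null_percentile(95)

    def test_confusion_rows_sum_to_one(self, rich):
        res = decode_numbers(rich, DecodingSpec(resamples=3, shuffle_resamples=3, seed=1))
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0, atol=1e-12)
        assert 0.0 <= res.mean_accuracy <= 1.0

    def test_trials_per_class_must_divide_folds(self):
        with pytest.raises(ValueError):
            DecodingSpec(trials_per_class=15, folds=10)

    def test_unbalanced_blocks_rejected(self):
        X = np.zeros((30, 2))
        y = np.array([0] * 20 + [1] * 10)
        with pytest.raises(ValueError):
            cv_accuracy(X, y)


class TestCrossProtocol:
    def test_protocol_invariant_code_transfers(self, rich):
        spec = DecodingSpec(trials_per_class=10, resamples=4, shuffle_resamples=2, seed=0)
        out = cross_protocol_decode(rich, spec)
        within = np.mean(
            [out["accuracies"][("dot", "dot")].mean(),
             out["accuracies"][("sign", "sign")].mean()]
        )
        across = np.mean(
            [out["accuracies"][("dot", "sign")].mean(),
             out["accuracies"][("sign", "dot")].mean()]
        )
        assert within > 0.35  # tuned population decodes well above 20% chance
        assert across > within - 0.12  # protocol-invariant tuning transfers

    def test_protocol_locked_code_does_not_transfer(self):
        # tuning expressed only in the dot protocol: across-protocol
        # decoding collapses to chance
        spec_pop = PopulationSpec(n_units=25, tuned_fraction=0.6,
                                  peak_gain_range=(12, 25), protocol_effect=0.0, seed=6)
        s, _ = generate_session(spec_pop, BehaviorParams(trials_per_cell=25), seed=6)
        spec = DecodingSpec(trials_per_class=10, resamples=4, shuffle_resamples=2, seed=0)
        out = cross_protocol_decode(s, spec)
        dot_within = out["accuracies"][("dot", "dot")].mean()
        across = out["accuracies"][("dot", "sign")].mean()
        assert dot_within > 0.4
        assert abs(across - 0.2) < 0.12


class TestErrorAndOutcome:
    def test_error_free_session_is_skipped(self):
        s, _ = generate_session(
            PopulationSpec(n_units=3, tuned_fraction=0.0, seed=0),
            BehaviorParams(weber_fraction=0.0, lapse_rate=0.0, trials_per_cell=12),
            seed=0,
        )
        with pytest.raises(ValueError, match="incorrect"):
            error_generalization(s, DecodingSpec(trials_per_class=10, resamples=2,
                                                 shuffle_resamples=0, seed=0))

    def test_outcome_confusion_rows_normalized(self):
        spec_pop = PopulationSpec(n_units=15, tuned_fraction=0.4,
                                  peak_gain_range=(10, 20), seed=8)
        s, _ = generate_session(
            spec_pop, BehaviorParams(weber_fraction=0.35, trials_per_cell=40), seed=8
        )
        res = outcome_classifier(
            s, DecodingSpec(trials_per_class=30, resamples=3, shuffle_resamples=3, seed=0)
        )
        assert res.classes == ["correct", "error_minus", "error_plus"]
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0, atol=1e-12)


def test_accuracy_increases_with_tuned_fraction():
    """Decoding accuracy is monotone in the fraction of tuned units."""
    accs = []
    for frac in (0.0, 0.25, 0.5):
        spec_pop = PopulationSpec(n_units=20, tuned_fraction=frac,
                                  peak_gain_range=(12, 25), seed=9)
        s, _ = generate_session(spec_pop, BehaviorParams(trials_per_cell=25), seed=9)
        res = decode_numbers(s, DecodingSpec(resamples=3, shuffle_resamples=0, seed=0))
        accs.append(res.mean_accuracy)
    assert accs[0] < accs[1] < accs[2]
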