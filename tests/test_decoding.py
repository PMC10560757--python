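"""Correlation decoder, CV protocol, and the size-matched subsampling sweep."""

import numpy as np
import pytest

from conftest import binomial_bounds, nn_corr_oracle
from laminar_decode import (
    DecodingConfig,
    DecodingResult,
    LayerProfile,
    cross_validated_accuracy,
    decoder_suite,
    generate_population,
    make_classifier,
    make_stimulus_set,
    nn_corr_fit,
    nn_corr_predict,
    subsampled_decode,
)


class TestNnCorr:
    def test_templates_are_class_means(self):
        X = np.array([[0.0, 1.0, 2.0], [2.0, 3.0, 4.0], [1.0, 0.0, 1.0]])
        y = np.array([0, 0, 1])
        classes, templates = nn_corr_fit(X, y)
        assert list(classes) == [0, 1]
        assert np.allclose(templates[0], [1.0, 2.0, 3.0])
        assert np.allclose(templates[1], [1.0, 0.0, 1.0])

    def test_single_trial_per_class_templates(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        classes, templates = nn_corr_fit(X, [5, 7])
        assert np.allclose(templates, X)

    def test_predict_recovers_template_class(self):
        X = np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0], [1.0, 2.0, 0.0]])
        y = np.array([0, 1, 2])
        classes, templates = nn_corr_fit(X, y)
        assert list(nn_corr_predict(classes, templates, X)) == [0, 1, 2]

    def test_anticorrelated_vector_avoids_its_template(self):
        templates = np.array([[0.0, 1.0, 2.0], [1.5, 1.2, 1.0]])
        classes = np.array([0, 1])
        pred = nn_corr_predict(classes, templates, -templates[0][None, :])
        assert pred[0] == 1

    def test_dimension_mismatch_rejected(self):
        classes, templates = nn_corr_fit(np.eye(3), [0, 1, 2])
        with pytest.raises(ValueError):
            nn_corr_predict(classes, templates, np.ones((1, 4)))

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """100 random small instances: <= 5 neurons, <= 4 classes, <= 6 train
        trials per class; predictions must agree exactly with a brute-force
        correlation oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_neurons = rng.integers(2, 6)
            n_classes = rng.integers(2, 5)
            n_train = rng.integers(1, 7)
            train_X, train_y = [], []
            for c in range(n_classes):
                for _ in range(n_train):
                    train_X.append(rng.normal(size=n_neurons))
                    train_y.append(c)
            train_X = np.array(train_X)
            train_y = np.array(train_y)
            test_X = rng.normal(size=(8, n_neurons))
            classes, templates = nn_corr_fit(train_X, train_y)
            pred = nn_corr_predict(classes, templates, test_X)
            oracle = nn_corr_oracle(train_X.tolist(), train_y.tolist(), test_X.tolist())
            assert list(pred) == oracle

    @pytest.mark.parametrize("a, b", [(0.5, 1.3), (3.0, -0.7)])
    def test_affine_rescaling_invariance(self, a, b):
        """Pearson invariance: a positive affine rescaling applied uniformly
        to templates and test vectors leaves predictions unchanged."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        y = np.repeat([0, 1, 2], 4)
        test = rng.normal(size=(5, 6))
        c1, t1 = nn_corr_fit(X, y)
        c2, t2 = nn_corr_fit(a * X + b, y)
        assert np.array_equal(
            nn_corr_predict(c1, t1, test), nn_corr_predict(c2, t2, a * test + b)
        )


class TestCrossValidation:
    @pytest.mark.parametrize(
        "decoder", ["svm-ecoc", "knn", "decision-tree", "naive-bayes", "logistic", "nn-corr"]
    )
    def test_separable_data_decodes_perfectly(self, decoder):
        stim = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 10})
        profile = LayerProfile(
            n_neurons=16, layer_label="L4", noise_sd=0.01, tuning_kappa=3.0,
            direction_mix=1.0, gain=1.0,
        )
        t = generate_population([profile], stim, seed=1)
        config = DecodingConfig(decoder=decoder, population_size=16, seed=3)
        accs = cross_validated_accuracy(t, None, config)
        assert accs == [1.0] * config.cv_folds

    def test_gain_zero_population_is_at_chance(self):
        stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 30})
        profile = LayerProfile(n_neurons=32, layer_label="L4", gain=0.0)
        t = generate_population([profile], stim, seed=17)
        config = DecodingConfig(decoder="nn-corr", population_size=32, seed=9)
        accs = cross_validated_accuracy(t, None, config)
        n_test = stim.n_conditions * stim.n_repeats
        correct = round(float(np.mean(accs)) * n_test)
        lo, hi = binomial_bounds(n_test, 1.0 / stim.n_conditions, alpha=0.01)
        assert lo <= correct <= hi

    def test_condition_with_too_few_repeats_rejected(self):
        stim = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 3})
        profile = LayerProfile(n_neurons=8, layer_label="L4")
        t = generate_population([profile], stim, seed=1)
        config = DecodingConfig(decoder="nn-corr", population_size=8, cv_folds=5, seed=1)
        with pytest.raises(ValueError, match="repeats"):
            cross_validated_accuracy(t, None, config)

    def test_holdout_used_for_non_default_test_fraction(self):
        stim = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 20})
        profile = LayerProfile(n_neurons=12, layer_label="L4")
        t = generate_population([profile], stim, seed=4)
        config = DecodingConfig(
            decoder="nn-corr", population_size=12, test_fraction=0.5, seed=2
        )
        accs = cross_validated_accuracy(t, None, config)
        assert len(accs) == config.cv_folds
        assert all(0.0 <= a <= 1.0 for a in accs)


@pytest.fixture(scope="module")
def population():
    stim = make_stimulus_set("custom", {"n_directions": 4, "n_repeats": 15})
    profile = LayerProfile(n_neurons=40, layer_label="L4", noise_sd=0.6)
    return generate_population([profile], stim, seed=77)


class TestSubsampledDecode:

    def test_pooled_accuracy_count(self, population):
        config = DecodingConfig(
            decoder="nn-corr", population_size=10, n_selection_repeats=15, seed=1
        )
        result = subsampled_decode(population, config)
        assert len(result.accuracies) == 15 * 5

    def test_full_population_repeats_are_identical(self, population):
        config = DecodingConfig(
            decoder="nn-corr", population_size=40, n_selection_repeats=3, seed=1
        )
        result = subsampled_decode(population, config)
        folds = np.array(result.accuracies).reshape(3, 5)
        assert np.array_equal(folds[0], folds[1])
        assert np.array_equal(folds[0], folds[2])

    def test_deterministic_under_fixed_seed(self, population):
        config = DecodingConfig(
            decoder="nn-corr", population_size=12, n_selection_repeats=4, seed=8
        )
        a = subsampled_decode(population, config)
        b = subsampled_decode(population, config)
        assert a.accuracies == b.accuracies
        assert a.mean_accuracy == b.mean_accuracy

    def test_oversized_population_rejected(self, population):
        config = DecodingConfig(decoder="nn-corr", population_size=41, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            subsampled_decode(population, config)

    def test_result_statistics(self):
        r = DecodingResult(accuracies=[0.2, 0.4, 0.6])
        assert r.mean_accuracy == pytest.approx(0.4)
        assert r.sem_accuracy == pytest.approx(0.2 / np.sqrt(3.0))
        with pytest.raises(ValueError):
            DecodingResult(accuracies=[1.2])


class TestDecoderSuite:
    def test_accuracy_grows_with_population_size(self):
        stim = make_stimulus_set("custom", {"n_directions": 8, "n_repeats": 25})
        profile = LayerProfile(n_neurons=260, layer_label="L4")
        t = generate_population([profile], stim, seed=31)
        config = DecodingConfig(decoder="nn-corr", population_size=4, seed=6)
        table = decoder_suite(t, [4, 256], ["nn-corr"], config)
        small, large = table["mean_accuracy"]
        assert large >= small

    def test_single_cell_table(self, small_population):
        config = DecodingConfig(
            decoder="nn-corr", population_size=8, n_selection_repeats=2, seed=4
        )
        table = decoder_suite(small_population, [8], ["nn-corr"], config)
        assert len(table) == 1
        assert table["n_accuracies"].iloc[0] == 2 * 5

    def test_suite_agrees_with_manual_nn_corr(self):
        stim = make_stimulus_set("custom", {"n_directions": 2, "n_repeats": 10})
        profile = LayerProfile(n_neurons=6, layer_label="L4", noise_sd=0.2)
        t = generate_population([profile], stim, seed=12)
        config = DecodingConfig(
            decoder="nn-corr", population_size=6, n_selection_repeats=1, seed=9
        )
        table = decoder_suite(t, [6], ["nn-corr"], config)
        manual = subsampled_decode(t, config)
        assert table["accuracies"].iloc[0] == manual.accuracies

    def test_unsorted_sizes_rejected(self, small_population):
        config = DecodingConfig(decoder="nn-corr", population_size=4, seed=1)
        with pytest.raises(ValueError):
            decoder_suite(small_population, [16, 4], ["nn-corr"], config)

    def test_unknown_decoder_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("perceptron", n_classes=4, seed=0)
        with pytest.raises(ValueError):
            DecodingConfig(decoder="perceptron")
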