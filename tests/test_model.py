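import numpy as np
import pytest

from premirna.model import (
    BaggedModel,
    BaggingConfig,
    ConfusionCounts,
    ModelError,
    bag_predict,
    bag_train,
    confusion,
    cross_validate_roc,
    f_score,
    metrics,
    rank_features,
)


class TestFScore:
    def test_identical_classes_score_zero(self):
        assert f_score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_direct_formula_oracle(self):
        # hand evaluation: means 2 and 8, overall 5; numerator (2-5)^2 +
        # (8-5)^2 = 18; unbiased scatters 1 + 1; F = 9
        assert f_score([1, 2, 3], [7, 8, 9]) == pytest.approx(9.0)

    def test_separated_constant_classes_are_infinite(self):
        assert f_score([2, 2, 2, 2], [0, 0, 0, 0]) == float("inf")

    def test_affine_invariance(self, rng):
        pos = rng.normal(3.0, 1.0, 30)
        neg = rng.normal(0.0, 1.5, 30)
        base = f_score(pos, neg)
        assert f_score(5 * pos + 2, 5 * neg + 2) == pytest.approx(base)

    def test_small_class_is_an_error(self):
        with pytest.raises(ModelError):
            f_score([1.0], [0.0, 1.0])

    def test_top_ranked_features_recover_planted_signal(self, rng):
        # positives and negatives differ only in columns 3 and 7
        n = 40
        X = rng.normal(0, 1, (2 * n, 10))
        y = np.array([1] * n + [0] * n)
        X[:n, 3] += 3.0
        X[:n, 7] -= 3.0
        scores = rank_features(X, y)
        assert set(np.argsort(scores)[-2:]) == {3, 7}


def _toy_data(rng, n=40, d=6, sep=3.0):
    X = np.vstack([
        rng.normal(0, 1, (n // 2, d)) + sep,
        rng.normal(0, 1, (n // 2, d)),
    ])
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    return X, y


class TestBagTrain:
    def test_separable_data_fits_perfectly(self, rng):
        X, y = _toy_data(rng)
        model = bag_train(X, y, BaggingConfig(n_bags=3, seed=1))
        labels, _ = model.predict(X)
        assert (labels == y).mean() == 1.0

    def test_same_seed_reproduces_predictions(self, rng):
        X, y = _toy_data(rng, sep=1.0)
        a = bag_train(X, y, BaggingConfig(n_bags=4, seed=7))
        b = bag_train(X, y, BaggingConfig(n_bags=4, seed=7))
        assert np.array_equal(a.predict(X)[1], b.predict(X)[1])

    def test_single_class_is_an_error(self, rng):
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ModelError):
            bag_train(X, np.ones(10, dtype=int))

    def test_nan_rejected(self):
        X = np.array([[np.nan, 1.0], [0.0, 1.0], [2.0, 0.0], [3.0, 1.0]])
        with pytest.raises(ModelError):
            bag_train(X, np.array([1, 1, 0, 0]))

    def test_committee_size(self, rng):
        X, y = _toy_data(rng)
        model = bag_train(X, y, BaggingConfig(n_bags=5, seed=0))
        assert len(model.members) == 15  # K x 3 learners

    def test_more_bags_reduce_accuracy_variance(self, rng):
        # simulation: on noisy data, the K=10 committee's held-out accuracy
        # varies less across resampled worlds than the K=1 committee's
        accs = {1: [], 10: []}
        for rep in range(15):
            local = np.random.default_rng(100 + rep)
            X, y = _toy_data(local, n=60, d=4, sep=0.8)
            Xt, yt = _toy_data(local, n=60, d=4, sep=0.8)
            for k in accs:
                m = bag_train(X, y, BaggingConfig(n_bags=k, seed=rep))
                labels, _ = m.predict(Xt)
                accs[k].append((labels == yt).mean())
        assert np.var(accs[10]) <= np.var(accs[1])


class _Stub:
    def __init__(self, vote):
        self.vote = vote

    def predict(self, X):
        return np.full(len(X), self.vote)


def _stub_model(votes):
    return BaggedModel(
        members=[("stub", None, _Stub(v)) for v in votes],
        n_features=2,
        config=BaggingConfig(n_bags=len(votes) // 3 or 1),
    )


class TestVoteRule:
    def test_unanimous_positive_scores_one(self):
        label, frac = bag_predict(_stub_model([1] * 6), np.zeros(2))
        assert (label, frac) == (1, 1.0)

    def test_unanimous_negative_scores_zero(self):
        label, frac = bag_predict(_stub_model([0] * 6), np.zeros(2))
        assert (label, frac) == (0, 0.0)

    def test_exact_tie_goes_negative(self):
        label, frac = bag_predict(_stub_model([1, 1, 1, 0, 0, 0]), np.zeros(2))
        assert frac == 0.5 and label == 0

    def test_threshold_consistency_with_vote_fraction(self):
        for votes in ([1, 0, 0], [1, 1, 0], [1, 1, 1, 1, 0, 0]):
            label, frac = bag_predict(_stub_model(votes), np.zeros(2))
            assert label == int(frac > 0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ModelError):
            bag_predict(_stub_model([1, 1, 1]), np.zeros(5))


class TestMetrics:
    def test_sensitivity_and_mcc_from_printed_confusion(self):
        m = metrics(ConfusionCounts(tp=449, fn=51, tn=556, fp=51))
        assert m["Sn"] == pytest.approx(89.80, abs=0.005)
        assert m["MCC"] == pytest.approx(0.81, abs=0.005)

    def test_accuracy_from_printed_confusion(self):
        m = metrics(ConfusionCounts(tp=184, fn=12, tn=161, fp=13))
        assert m["Acc"] == pytest.approx(93.24, abs=0.005)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
        assert m["Sn"] == m["Sp"] == m["Acc"] == 100.0
        assert m["MCC"] == pytest.approx(1.0)

    def test_accuracy_identity_and_symmetry(self):
        c = ConfusionCounts(tp=30, fn=10, tn=25, fp=15)
        m = metrics(c)
        assert m["Acc"] == pytest.approx(100.0 * (30 + 25) / 80)
        swapped = metrics(ConfusionCounts(tp=c.tn, fn=c.fp, tn=c.tp, fp=c.fn))
        assert swapped["Acc"] == pytest.approx(m["Acc"])
        assert swapped["Sn"] == pytest.approx(m["Sp"])

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ModelError):
            metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))

    def test_confusion_counting(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


class TestCrossValidation:
    def test_separable_data_has_unit_auc(self, rng):
        X, y = _toy_data(rng, n=40, sep=4.0)
        _, _, auc_value = cross_validate_roc(X, y, folds=5,
                                             cfg=BaggingConfig(n_bags=3, seed=0))
        assert auc_value == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_auc(self, rng):
        X, y = _toy_data(rng, n=60, sep=3.0)
        y_shuffled = rng.permutation(y)
        _, _, auc_value = cross_validate_roc(
            X, y_shuffled, folds=5, cfg=BaggingConfig(n_bags=3, seed=0)
        )
        assert 0.4 <= auc_value <= 0.6 or abs(auc_value - 0.5) <= 0.1

    def test_too_few_samples_per_class_rejected(self, rng):
        X, y = _toy_data(rng, n=10)
        with pytest.raises(ModelError):
            cross_validate_roc(X, y, folds=10)

    def test_model_save_load_round_trip(self, tmp_path, rng):
        X, y = _toy_data(rng)
        model = bag_train(X, y, BaggingConfig(n_bags=2, seed=3))
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = BaggedModel.load(path)
        assert np.array_equal(loaded.predict(X)[1], model.predict(X)[1])
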