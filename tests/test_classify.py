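import numpy as np
import pytest
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from nirsbci.containers import BL, MA, ConfigurationError, ProtocolError
from nirsbci.classify import (
    CVScheme,
    crossvalidate,
    ledoit_wolf_gamma,
    make_splits,
    splits_table,
    train_linsvm,
    train_meta,
    train_slda,
)
from nirsbci.features import FeatureMatrix


def _labels(n_ma, n_bl):
    return np.array([MA] * n_ma + [BL] * n_bl, dtype=object)


def _gaussian_problem(rng, n_per_class=30, d=6, sep=1.0):
    mix = rng.standard_normal((d, d))
    X = rng.standard_normal((2 * n_per_class, d)) @ mix
    y = _labels(n_per_class, n_per_class)
    X[y == MA] += sep
    return X, y


class TestLedoitWolf:
    def test_large_n_small_d_gives_small_gamma(self, rng):
        # anisotropic covariance: far from the spherical shrinkage target,
        # so with n >> d the analytic intensity must be near zero
        X = rng.standard_normal((2000, 4)) * np.array([3.0, 1.0, 0.5, 0.2])
        y = _labels(1000, 1000)
        assert ledoit_wolf_gamma(X, y) < 0.2

    def test_high_dim_gamma_positive_and_cov_invertible(self, rng):
        X = rng.standard_normal((10, 40))
        y = _labels(5, 5)
        gamma = ledoit_wolf_gamma(X, y)
        assert gamma > 0.0
        model = train_slda(X, y, gamma=gamma)      # solve succeeds
        assert np.all(np.isfinite(model.weights))

    def test_clipped_to_unit_interval(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((6, 12))
            y = _labels(3, 3)
            assert 0.0 <= ledoit_wolf_gamma(X, y) <= 1.0

    def test_matches_sklearn_on_class_centered_data(self, rng):
        X, y = _gaussian_problem(rng)
        Xc = np.concatenate(
            [X[y == MA] - X[y == MA].mean(axis=0), X[y == BL] - X[y == BL].mean(axis=0)]
        )
        expected = ledoit_wolf_shrinkage(Xc, assume_centered=True)
        assert ledoit_wolf_gamma(X, y) == pytest.approx(expected, abs=1e-12)

    def test_requires_two_samples_per_class(self, rng):
        with pytest.raises(ConfigurationError):
            ledoit_wolf_gamma(rng.standard_normal((3, 2)), _labels(1, 2))


class TestShrinkageLDA:
    def test_gamma_zero_equals_classic_lda(self, rng):
        X, y = _gaussian_problem(rng, n_per_class=40, d=5)
        model = train_slda(X, y, gamma=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None).fit(X, y.astype(str))
        assert np.abs(model.weights - sk.coef_.ravel()).max() < 1e-8
        assert model.bias == pytest.approx(sk.intercept_[0], abs=1e-8)

    def test_point_classes_symmetric_midpoint(self):
        mu = np.array([1.0, 2.0])
        X = np.array([mu, mu, -mu, -mu])
        y = _labels(2, 2)
        model = train_slda(X, y, gamma=1.0)
        parallel = model.weights[0] * mu[1] - model.weights[1] * mu[0]
        assert parallel == pytest.approx(0.0)    # w parallel to mu
        assert model.decision(np.zeros((1, 2)))[0] == pytest.approx(0.0)

    def test_gamma_one_is_mean_difference_direction(self, rng):
        X, y = _gaussian_problem(rng)
        model = train_slda(X, y, gamma=1.0)
        diff = X[y == MA].mean(axis=0) - X[y == BL].mean(axis=0)
        ratio = model.weights / diff
        assert np.allclose(ratio, ratio[0]) and ratio[0] > 0

    def test_positive_decision_predicts_ma(self, rng):
        X, y = _gaussian_problem(rng, sep=3.0)
        model = train_slda(X, y)
        preds = model.predict(X)
        assert np.mean(preds == y) > 0.95


class TestLinearSVM:
    def test_separable_toy_margin(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0], [-2.0, 0.0]])
        y = _labels(2, 2)
        model = train_linsvm(X, y, cost=1e3)
        assert np.all(model.predict(X) == y)
        dv = model.decision(X)
        assert np.min(np.abs(dv)) >= 1.0 - 1e-6

    def test_label_flip_negates_weights(self, rng):
        X, y = _gaussian_problem(rng, n_per_class=15, d=3)
        a = train_linsvm(X, y)
        flipped = np.where(y == MA, BL, MA).astype(object)
        b = train_linsvm(X, flipped)
        assert np.abs(a.weights + b.weights).max() < 1e-2
        assert abs(a.bias + b.bias) < 1e-2

    def test_duplicated_dataset_invariance(self, rng):
        # separable regime (no active slack): doubling every row leaves the
        # margin problem, and hence the decision function, unchanged
        X, y = _gaussian_problem(rng, n_per_class=15, d=3, sep=6.0)
        a = train_linsvm(X, y)
        b = train_linsvm(np.vstack([X, X]), np.concatenate([y, y]))
        probe = rng.standard_normal((20, 3))
        assert np.abs(a.decision(probe) - b.decision(probe)).max() < 1e-6

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            train_linsvm(rng.standard_normal((4, 2)), _labels(4, 0))


class TestMetaClassifier:
    def test_perfect_base_plus_noise_base(self, rng):
        y = _labels(30, 30)
        dv_perfect = np.where(y == MA, 1.0, -1.0)
        dv_noise = rng.standard_normal(60)
        meta = train_meta(dv_perfect, dv_noise, y, kind="lda")
        acc = np.mean(meta.predict(np.column_stack([dv_perfect, dv_noise])) == y)
        assert acc >= 0.95

    def test_identical_bases_preserve_base_accuracy(self, rng):
        y = _labels(30, 30)
        dv = np.where(y == MA, 1.0, -1.0) + rng.standard_normal(60)
        base_acc = np.mean(np.where(dv > 0, MA, BL).astype(object) == y)
        meta = train_meta(dv, dv.copy(), y, kind="lda")
        meta_acc = np.mean(meta.predict(np.column_stack([dv, dv])) == y)
        assert meta_acc == pytest.approx(base_acc)

    def test_anticorrelated_errors_fuse_above_base(self):
        """Two 75%-accurate bases erring on disjoint trials fuse to >= 75%.

        Constructed contingency: 60 trials; base A errs on trials 0-14, base
        B errs on trials 15-29 (all MA); both are confident elsewhere.
        """
        y = _labels(30, 30)
        dv_a = np.where(y == MA, 2.0, -2.0).astype(float)
        dv_b = dv_a.copy()
        dv_a[:15] = -1.0
        dv_b[15:30] = -1.0
        base_acc = 0.75
        meta = train_meta(dv_a, dv_b, y, kind="lda")
        acc = np.mean(meta.predict(np.column_stack([dv_a, dv_b])) == y)
        assert acc >= base_acc

    def test_mismatched_trials_rejected(self):
        with pytest.raises(ProtocolError):
            train_meta(np.zeros(5), np.zeros(6), _labels(3, 3))


class TestSplits:
    def test_partition_and_balance(self):
        y = _labels(30, 30)
        splits = make_splits(y, CVScheme(seed=3))
        assert len(splits) == 10
        for folds in splits:
            seen = np.concatenate([te for _, te in folds])
            assert sorted(seen) == list(range(60))
            for _, te in folds:
                n_ma = np.sum(y[te] == MA)
                assert abs(n_ma - (len(te) - n_ma)) <= 1

    def test_seed_determinism(self):
        y = _labels(30, 30)
        a = make_splits(y, CVScheme(seed=5))
        b = make_splits(y, CVScheme(seed=5))
        assert splits_table(a).equals(splits_table(b))

    def test_too_few_trials_per_class_rejected(self):
        with pytest.raises(ProtocolError):
            make_splits(_labels(3, 30), CVScheme(n_folds=5))


def _features_by_anchor(rng, anchors=(0.0, 1.0), n_per_class=15, d=4, sep=0.0):
    labels = _labels(n_per_class, n_per_class)
    out = {}
    for a in anchors:
        fms = {}
        for c in ("hbo", "hbr"):
            X = rng.standard_normal((2 * n_per_class, d))
            X[labels == MA] += sep
            fms[c] = FeatureMatrix(X=X, labels=labels, anchor=a,
                                   columns=tuple(f"f{i}" for i in range(d)))
        out[a] = fms
    return out, labels


class TestCrossValidate:
    def test_accuracies_bounded_and_anchors_consistent(self, rng):
        fba, labels = _features_by_anchor(rng, sep=1.5)
        scheme = CVScheme(n_repeats=2, seed=1)
        res = crossvalidate(fba, labels, scheme)
        acc = res.accuracies
        assert acc.accuracy_pct.between(0, 100).all()
        anchors_by_set = acc.groupby("chromophores")["anchor_s"].unique()
        for anchors in anchors_by_set:
            assert sorted(anchors) == [0.0, 1.0]

    def test_identical_splits_across_classifiers_and_chromophores(self, rng):
        fba, labels = _features_by_anchor(rng)
        res = crossvalidate(fba, labels, CVScheme(n_repeats=2, seed=2))
        key = ["anchor_s", "repeat", "fold", "trial"]
        groups = {
            name: set(map(tuple, g[key].to_numpy()))
            for name, g in res.predictions.groupby(["classifier", "chromophores"])
        }
        reference = next(iter(groups.values()))
        assert all(g == reference for g in groups.values())

    def test_fixed_seed_bit_identical(self, rng):
        fba, labels = _features_by_anchor(rng)
        a = crossvalidate(fba, labels, CVScheme(n_repeats=2, seed=4))
        b = crossvalidate(fba, labels, CVScheme(n_repeats=2, seed=4))
        assert a.weight_hash == b.weight_hash
        assert a.accuracies.equals(b.accuracies)

    def test_leakage_guard_test_labels_do_not_touch_training(self, rng):
        """Randomizing test-fold labels at scoring time must leave every
        trained weight unchanged (verified via the weight digest), and must
        drive the measured accuracy to chance."""
        fba, labels = _features_by_anchor(rng, sep=2.0)
        scheme = CVScheme(n_repeats=2, seed=6)
        splits = make_splits(labels, scheme)
        clean = crossvalidate(fba, labels, scheme, splits=splits,
                              collect_predictions=False)
        audited = crossvalidate(fba, labels, scheme, splits=splits,
                                collect_predictions=False,
                                corrupt_test_labels=np.random.default_rng(0))
        assert clean.weight_hash == audited.weight_hash
        assert clean.accuracies.accuracy_pct.mean() > 80.0
        assert audited.accuracies.accuracy_pct.mean() < 70.0

    def test_chance_level_on_null_features(self, rng):
        fba, labels = _features_by_anchor(rng, sep=0.0, n_per_class=30)
        res = crossvalidate(fba, labels, CVScheme(n_repeats=3, seed=7),
                            classifiers=("lda",), chromo_sets=("hbr",),
                            collect_predictions=False)
        mean_acc = res.accuracies.accuracy_pct.mean()
        assert 35.0 < mean_acc < 65.0
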