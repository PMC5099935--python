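import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirsbci.classify import CVResult, CVScheme
from nirsbci.containers import BL, MA, ConfigurationError, DataError
from nirsbci.evaluate import (
    accuracy_curve,
    classifier_agreement_mi,
    compare_classifiers,
    max_accuracy,
    mutual_information,
    mutual_information_table,
    paired_test,
    regress_accuracy_on_mi,
)


def _cvresult(rows, preds=None):
    acc = pd.DataFrame(
        rows, columns=["anchor_s", "repeat", "fold", "classifier", "chromophores",
                       "accuracy_pct", "n_test"]
    )
    pred = pd.DataFrame(
        preds or [],
        columns=["anchor_s", "repeat", "fold", "classifier", "chromophores",
                 "trial", "y_true", "y_pred", "decision_value"],
    )
    return CVResult(accuracies=acc, predictions=pred, scheme=CVScheme())


class TestAccuracyCurve:
    def test_flat_extremes(self):
        rows = [(a, r, f, "lda", "hbr", acc, 12)
                for a in (0.0, 1.0) for r in range(2) for f in range(5)
                for acc in (100.0,)]
        curve = accuracy_curve(_cvresult(rows), "lda", "hbr")
        assert np.allclose(curve.values, 100.0)
        rows0 = [(a, r, f, "lda", "hbr", 0.0, 12)
                 for a in (0.0, 1.0) for r in range(2) for f in range(5)]
        assert np.allclose(accuracy_curve(_cvresult(rows0), "lda", "hbr").values, 0.0)

    def test_matches_manual_average(self, rng):
        rows = [(float(a), r, f, "lda", "hbr", float(rng.uniform(0, 100)), 12)
                for a in range(3) for r in range(4) for f in range(5)]
        res = _cvresult(rows)
        curve = accuracy_curve(res, "lda", "hbr")
        df = res.accuracies
        for a in range(3):
            manual = df[df.anchor_s == a].accuracy_pct.mean()
            assert curve[float(a)] == pytest.approx(manual)

    def test_missing_combination_rejected(self):
        res = _cvresult([(0.0, 0, 0, "lda", "hbr", 50.0, 12)])
        with pytest.raises(ConfigurationError):
            accuracy_curve(res, "svm", "hbo")


class TestMaxAccuracy:
    def test_monotone_curve_peaks_at_right_edge(self):
        curve = pd.Series(np.linspace(50, 90, 31), index=np.arange(-5.0, 26.0))
        value, anchor = max_accuracy(curve)
        assert anchor == 25.0 and value == pytest.approx(90.0)

    def test_constant_curve_earliest_anchor(self):
        curve = pd.Series(70.0, index=np.arange(-5.0, 26.0))
        value, anchor = max_accuracy(curve)
        assert (value, anchor) == (70.0, 5.0)

    def test_matches_brute_force_scan(self, rng):
        curve = pd.Series(rng.uniform(40, 95, 31), index=np.arange(-5.0, 26.0))
        value, anchor = max_accuracy(curve, (5.0, 25.0))
        in_range = {a: v for a, v in curve.items() if 5.0 <= a <= 25.0}
        best = max(in_range.values())
        assert value == pytest.approx(best)
        assert anchor == min(a for a, v in in_range.items() if v == best)
        assert value >= np.mean(list(in_range.values()))

    def test_empty_range_rejected(self):
        curve = pd.Series([60.0], index=[0.0])
        with pytest.raises(ConfigurationError):
            max_accuracy(curve, (5.0, 25.0))


class TestPairedTest:
    def test_identical_samples_degenerate(self):
        a = np.array([70.0, 72.0, 74.0])
        res = paired_test(a, a, kind="t")
        assert res.p == 1.0 and res.degenerate

    def test_wilcoxon_all_positive_exact(self):
        """Differences 1..6 all positive: W = 0 and exact two-sided p equals
        the enumeration over all 2^6 sign assignments."""
        diffs = np.arange(1.0, 7.0)
        res = paired_test(diffs + 10.0, np.full(6, 10.0), kind="wilcoxon")
        assert res.statistic == 0.0
        # enumerate the null distribution of W- over all sign assignments
        ranks = np.arange(1, 7)
        w_minus = [sum(r for r, s in zip(ranks, signs) if s < 0)
                   for signs in itertools.product([1, -1], repeat=6)]
        observed = 0
        p_exact = np.mean([min(w, sum(ranks) - w) <= observed for w in w_minus])
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_t_matches_reference_cdf(self, rng):
        a = rng.normal(75, 5, 11)
        b = a - rng.normal(2, 1, 11)
        res = paired_test(a, b, kind="t")
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert res.p == pytest.approx(expected, abs=1e-10)

    def test_wilcoxon_all_zero_differences_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_test(a, a, kind="wilcoxon")
        assert res.p == 1.0 and res.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            paired_test(np.ones(3), np.ones(4))


class TestMutualInformation:
    def test_identical_balanced_vectors_give_one_bit(self):
        v = np.array([MA] * 15 + [BL] * 15, dtype=object)
        assert mutual_information(v, v) == pytest.approx(1.0)

    def test_constant_vector_gives_zero(self, rng):
        a = np.full(20, MA, dtype=object)
        b = rng.choice([MA, BL], 20).astype(object)
        assert mutual_information(a, b) == pytest.approx(0.0)

    def test_printed_table_matches_hand_computation(self):
        table = np.array([[20.0, 10.0], [5.0, 25.0]])
        n = table.sum()
        mi = 0.0
        for i in range(2):
            for j in range(2):
                pxy = table[i, j] / n
                px = table[i].sum() / n
                py = table[:, j].sum() / n
                mi += pxy * np.log2(pxy / (px * py))
        assert mutual_information_table(table) == pytest.approx(mi, abs=1e-12)

    def test_symmetry_and_relabel_invariance(self, rng):
        a = rng.choice([MA, BL], 50).astype(object)
        b = rng.choice([MA, BL], 50).astype(object)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))
        swap = {MA: BL, BL: MA}
        a2 = np.array([swap[x] for x in a], dtype=object)
        b2 = np.array([swap[x] for x in b], dtype=object)
        assert mutual_information(a2, b2) == pytest.approx(mutual_information(a, b))

    def test_bounded_by_marginal_entropy(self, rng):
        a = rng.choice([MA, BL], 40, p=[0.7, 0.3]).astype(object)
        b = rng.choice([MA, BL], 40).astype(object)
        mi = mutual_information(a, b)
        h = lambda v: stats.entropy(pd.Series(v).value_counts(normalize=True), base=2)
        assert 0.0 <= mi <= min(h(a), h(b)) + 1e-12


class TestRegression:
    def test_collinear_points_zero_residual(self):
        mi = np.linspace(0.1, 0.9, 8)
        acc = 50 + 30 * mi
        slope, intercept = regress_accuracy_on_mi(mi, acc)
        assert slope == pytest.approx(30.0) and intercept == pytest.approx(50.0)

    def test_two_points_exact_line(self):
        slope, intercept = regress_accuracy_on_mi([0.2, 0.8], [60.0, 90.0])
        assert slope == pytest.approx(50.0) and intercept == pytest.approx(50.0)

    def test_matches_normal_equations(self, rng):
        mi = rng.uniform(0, 1, 30)
        acc = 55 + 25 * mi + rng.normal(0, 3, 30)
        slope, intercept = regress_accuracy_on_mi(mi, acc)
        A = np.column_stack([mi, np.ones_like(mi)])
        ref = np.linalg.lstsq(A, acc, rcond=None)[0]
        assert slope == pytest.approx(ref[0], abs=1e-10)
        assert intercept == pytest.approx(ref[1], abs=1e-10)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ConfigurationError):
            regress_accuracy_on_mi([0.5, 0.5], [60.0, 70.0])


class TestCompareClassifiers:
    def test_equal_accuracies(self):
        acc = {f"S{i}": 70.0 + i for i in range(5)}
        comp = compare_classifiers(acc, dict(acc))
        assert comp.fraction_lda_higher == 0.0
        assert comp.p == 1.0 and comp.degenerate

    def test_uniform_advantage(self):
        lda = {f"S{i}": 75.0 + i for i in range(5)}
        svm = {k: v - 5.0 for k, v in lda.items()}
        comp = compare_classifiers(lda, svm)
        assert comp.fraction_lda_higher == 1.0
        assert comp.p < 0.05

    def test_fraction_matches_enumeration(self, rng):
        lda = {f"S{i}": float(rng.uniform(50, 95)) for i in range(9)}
        svm = {f"S{i}": float(rng.uniform(50, 95)) for i in range(9)}
        comp = compare_classifiers(lda, svm)
        brute = sum(lda[k] > svm[k] for k in lda) / len(lda)
        assert comp.fraction_lda_higher == pytest.approx(brute)


class TestAgreementMI:
    def test_mi_tracks_accuracy_across_engineered_subjects(self):
        """Subjects engineered with higher separability show higher LDA-SVM
        output agreement (rank correlation > 0), the qualitative
        MI-vs-accuracy relationship."""
        from nirsbci.classify import crossvalidate
        from nirsbci.features import FeatureMatrix

        rng = np.random.default_rng(21)
        labels = np.array([MA] * 20 + [BL] * 20, dtype=object)
        seps = np.linspace(0.0, 2.0, 8)
        mis, accs = [], []
        for sep in seps:
            fms = {}
            for c in ("hbo", "hbr"):
                X = rng.standard_normal((40, 6))
                X[labels == MA] += sep
                fms[c] = FeatureMatrix(X=X, labels=labels, anchor=10.0,
                                       columns=tuple(f"f{i}" for i in range(6)))
            res = crossvalidate({10.0: fms}, labels, CVScheme(n_repeats=3, seed=int(sep * 10)),
                                chromo_sets=("hbr",))
            mi = classifier_agreement_mi(res, "hbr", anchor_range=(9.0, 13.0))
            acc = res.accuracies.accuracy_pct.mean()
            mis.append(mi)
            accs.append(acc)
        rho = stats.spearmanr(mis, accs).statistic
        assert rho > 0
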