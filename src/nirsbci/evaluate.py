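"""Group-level summaries of cross-validated accuracies.

Covers: per-anchor accuracy curves and grand averages, per-subject maximum
accuracy in the 5-25 s post-onset range (hemodynamic delay), paired tests
between paradigms (t and Wilcoxon signed-rank), LDA-vs-SVM comparison in a
peak window, plug-in mutual information between the two classifiers'
predicted labels with its regression against accuracy, and questionnaire
statistics (Wilcoxon on 5-point ratings).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CVResult
from .containers import ConfigurationError, DataError

__all__ = [
    "accuracy_curve",
    "subject_curves",
    "max_accuracy",
    "paired_test",
    "mutual_information",
    "mutual_information_table",
    "classifier_agreement_mi",
    "regress_accuracy_on_mi",
    "compare_classifiers",
]

WILCOXON_EXACT_MAX_N = 12


def accuracy_curve(
    result: CVResult, classifier: str, chromophores: str
) -> pd.Series:
    """Mean accuracy (%) per anchor over all fold evaluations."""
    df = result.accuracies
    sel = df[(df.classifier == classifier) & (df.chromophores == chromophores)]
    if sel.empty:
        raise ConfigurationError(
            f"no results for classifier={classifier}, chromophores={chromophores}"
        )
    return sel.groupby("anchor_s")["accuracy_pct"].mean()


def subject_curves(
    results: Dict[str, CVResult], classifier: str, chromophores: str
) -> pd.DataFrame:
    """Anchor x subject table of mean accuracies; column order = dict order."""
    return pd.DataFrame(
        {sid: accuracy_curve(res, classifier, chromophores) for sid, res in results.items()}
    )


def grand_average(curves: pd.DataFrame) -> pd.Series:
    """Grand-average curve: mean over subjects per anchor."""
    return curves.mean(axis=1)


def max_accuracy(
    curve: pd.Series, anchor_range: Tuple[float, float] = (5.0, 25.0)
) -> Tuple[float, float]:
    """(max accuracy %, earliest attaining anchor) within ``anchor_range``."""
    lo, hi = anchor_range
    sel = curve[(curve.index >= lo) & (curve.index <= hi)]
    if sel.empty:
        raise ConfigurationError(f"no anchors inside [{lo}, {hi}] s")
    best = sel.max()
    anchor = float(sel.index[sel.values >= best - 1e-12][0])
    return float(best), anchor


@dataclass
class PairedTestResult:
    p: float
    statistic: float
    kind: str
    degenerate: bool = False          # all differences zero / zero variance


def paired_test(
    acc_a: Sequence[float], acc_b: Sequence[float], kind: str = "t"
) -> PairedTestResult:
    """Two-sided paired test between matched per-subject values.

    ``kind="t"``: one-sample t on the differences (p = 1, flagged, when the
    differences have zero variance).  ``kind="wilcoxon"``: signed-rank with
    zero differences dropped; exact distribution for n <= 12 non-zero
    differences, normal approximation with continuity correction above.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired samples must have equal length")
    d = a - b
    if kind == "t":
        if a.size < 2:
            raise ConfigurationError("paired t-test needs n >= 2")
        if np.allclose(d.std(ddof=1), 0.0):
            # constant differences: identical samples give p = 1; a constant
            # nonzero shift is perfectly consistent, so p -> 0 (flagged)
            if np.allclose(d.mean(), 0.0):
                return PairedTestResult(p=1.0, statistic=0.0, kind="t", degenerate=True)
            return PairedTestResult(
                p=0.0, statistic=float(np.sign(d.mean()) * np.inf), kind="t", degenerate=True
            )
        t, p = stats.ttest_rel(a, b)
        return PairedTestResult(p=float(p), statistic=float(t), kind="t")
    if kind == "wilcoxon":
        nz = d[d != 0]
        if nz.size == 0:
            return PairedTestResult(p=1.0, statistic=0.0, kind="wilcoxon", degenerate=True)
        method = "exact" if nz.size <= WILCOXON_EXACT_MAX_N else "approx"
        res = stats.wilcoxon(
            nz, zero_method="wilcox", correction=(method == "approx"), method=method
        )
        return PairedTestResult(p=float(res.pvalue), statistic=float(res.statistic), kind="wilcoxon")
    raise ConfigurationError(f"unknown test kind {kind!r}")


def mutual_information(preds_a: Sequence, preds_b: Sequence) -> float:
    """Plug-in mutual information (bits) between two label vectors.

    Empirical joint distribution over the observed label pairs; the
    convention 0*log(0) = 0 applies.  Symmetric, non-negative, bounded by
    the smaller marginal entropy.
    """
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    if a.shape != b.shape or a.size == 0:
        raise DataError("prediction vectors must be equal-length and non-empty")
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    return mutual_information_table(joint)


def mutual_information_table(joint: np.ndarray) -> float:
    """MI in bits from a contingency table of counts."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    if n <= 0:
        raise DataError("empty contingency table")
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return float(np.nansum(terms))


def classifier_agreement_mi(
    result: CVResult,
    chromophores: str,
    anchor_range: Tuple[float, float] = (9.0, 13.0),
    classifiers: Tuple[str, str] = ("lda", "svm"),
) -> float:
    """MI (bits) between two classifiers' pooled test predictions.

    Predictions are pooled over all folds, repeats and anchors inside
    ``anchor_range`` (hard labels; both classifiers saw identical splits so
    the pooled vectors are aligned trial-by-trial).
    """
    df = result.predictions
    sel = df[
        (df.chromophores == chromophores)
        & (df.anchor_s >= anchor_range[0])
        & (df.anchor_s <= anchor_range[1])
    ]
    key = ["anchor_s", "repeat", "fold", "trial"]
    a = sel[sel.classifier == classifiers[0]].set_index(key)["y_pred"]
    b = sel[sel.classifier == classifiers[1]].set_index(key)["y_pred"]
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1).dropna()
    if joined.empty:
        raise ConfigurationError("no overlapping predictions for the two classifiers")
    return mutual_information(joined["a"].to_numpy(), joined["b"].to_numpy())


def regress_accuracy_on_mi(
    mi: Sequence[float], accuracy: Sequence[float]
) -> Tuple[float, float]:
    """OLS of accuracy (%) on MI (bits): returns (slope, intercept)."""
    mi = np.asarray(mi, dtype=float)
    acc = np.asarray(accuracy, dtype=float)
    if mi.size < 2 or np.allclose(mi, mi[0]):
        raise ConfigurationError("need >= 2 distinct MI values for a regression")
    res = stats.linregress(mi, acc)
    return float(res.slope), float(res.intercept)


@dataclass
class ClassifierComparison:
    pairs: pd.DataFrame               # subject, acc_lda, acc_svm
    fraction_lda_higher: float        # strictly above the diagonal
    p: float
    degenerate: bool


def compare_classifiers(
    lda_acc: Dict[str, float],
    svm_acc: Dict[str, float],
    kind: str = "t",
) -> ClassifierComparison:
    """Scatter-style LDA vs SVM comparison over matched subject accuracies."""
    if set(lda_acc) != set(svm_acc):
        raise DataError("LDA and SVM records must cover the same subjects")
    subjects = sorted(lda_acc)
    a = np.array([lda_acc[s] for s in subjects])
    b = np.array([svm_acc[s] for s in subjects])
    frac = float(np.mean(a > b))
    test = paired_test(a, b, kind=kind)
    pairs = pd.DataFrame({"subject": subjects, "acc_lda": a, "acc_svm": b})
    return ClassifierComparison(
        pairs=pairs, fraction_lda_higher=frac, p=test.p, degenerate=test.degenerate
    )


def window_mean_accuracy(
    result: CVResult,
    classifier: str,
    chromophores: str,
    anchor_range: Tuple[float, float] = (9.0, 13.0),
) -> float:
    """Mean accuracy (%) over anchors inside ``anchor_range``."""
    curve = accuracy_curve(result, classifier, chromophores)
    sel = curve[(curve.index >= anchor_range[0]) & (curve.index <= anchor_range[1])]
    if sel.empty:
        raise ConfigurationError(f"no anchors inside {anchor_range}")
    return float(sel.mean())
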