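"""Linear classification of MA vs BL features and the CV protocol.

Two linear classifiers are supported:

* shrinkage LDA: ``w = S~^-1 (mu_MA - mu_BL)`` with the pooled within-class
  covariance shrunk toward a scaled identity, ``S~ = (1-g) S + g nu I``,
  ``nu = trace(S)/d``.  The shrinkage intensity ``g`` defaults to the
  analytic Ledoit-Wolf estimate computed from class-centered data.
* linear soft-margin SVM (backed by scikit-learn's SVC with a linear
  kernel), cost fixed at 1.0 by default.

MA is the positive class everywhere: decision value > 0 predicts MA.

Chromophore fusion ("both") is a meta-classification: a 2-feature linear
classifier of the same kind is trained on the decision values of the
HbO-based and HbR-based base classifiers.  To keep the meta weights
unbiased they are fitted on out-of-fold base outputs from an inner
stratified split of the training data; at test time the bases are trained
on the full training set.

The evaluation protocol is 10 repeats of stratified 5-fold cross-validation
with splits drawn once per repeat from the scheme seed and reused across
classifiers, chromophore sets and window anchors, so all models provably
see identical training and test samples.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import BL, MA, ConfigurationError, ProtocolError
from .features import FeatureMatrix, Normalization, normalize_apply, normalize_fit

__all__ = [
    "LinearModel",
    "CVScheme",
    "CVResult",
    "ledoit_wolf_gamma",
    "train_slda",
    "train_linsvm",
    "train_meta",
    "make_splits",
    "crossvalidate",
    "CHROMO_SETS",
]

CHROMO_SETS = ("hbr", "hbo", "both")
CLASSIFIERS = ("lda", "svm")


@dataclass
class LinearModel:
    """A linear decision function d(x) = w.x + b; d > 0 predicts MA."""

    weights: np.ndarray
    bias: float
    kind: str                         # "lda" or "svm"
    gamma: Optional[float] = None     # shrinkage intensity, LDA only

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) > 0, MA, BL).astype(object)


def _class_split(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    Xma, Xbl = X[y == MA], X[y == BL]
    if len(Xma) == 0 or len(Xbl) == 0:
        raise ConfigurationError("both classes must be present")
    return Xma, Xbl


def ledoit_wolf_gamma(X: np.ndarray, y: np.ndarray) -> float:
    """Analytic Ledoit-Wolf shrinkage intensity toward nu*I.

    Computed from class-centered data: each sample has its class mean
    removed, then the standard Ledoit-Wolf estimate for centered data is
    applied.  Result clipped to [0, 1].
    """
    X = np.asarray(X, dtype=float)
    Xma, Xbl = _class_split(X, y)
    if len(Xma) < 2 or len(Xbl) < 2:
        raise ConfigurationError("need >= 2 samples per class")
    Xc = np.concatenate([Xma - Xma.mean(axis=0), Xbl - Xbl.mean(axis=0)], axis=0)
    n, d = Xc.shape
    S = Xc.T @ Xc / n
    nu = np.trace(S) / d
    delta2 = np.sum((S - nu * np.eye(d)) ** 2) / d
    # E ||x x' - S||^2_F / n, the variance of the sample covariance entries
    x2 = Xc**2
    beta2 = (np.sum(x2.T @ x2) / n - np.sum(S**2)) / (n * d)
    if delta2 <= 0:
        return 0.0
    gamma = beta2 / delta2
    return float(np.clip(gamma, 0.0, 1.0))


def train_slda(
    X: np.ndarray, y: np.ndarray, gamma: Optional[float] = None
) -> LinearModel:
    """Shrinkage LDA with the covariance shrunk toward a scaled identity.

    ``gamma=None`` uses the Ledoit-Wolf estimate; ``gamma=0`` is classic
    LDA (requires a well-conditioned covariance); ``gamma=1`` reduces to
    the class-mean-difference (nearest-mean) direction.
    """
    X = np.asarray(X, dtype=float)
    Xma, Xbl = _class_split(X, y)
    if gamma is None:
        gamma = ledoit_wolf_gamma(X, y)
    if not 0.0 <= gamma <= 1.0:
        raise ConfigurationError("gamma must lie in [0, 1]")
    mu1, mu2 = Xma.mean(axis=0), Xbl.mean(axis=0)
    Xc = np.concatenate([Xma - mu1, Xbl - mu2], axis=0)
    n, d = Xc.shape
    S = Xc.T @ Xc / n
    nu = np.trace(S) / d
    if nu == 0.0:
        nu = 1.0          # zero within-class scatter: fall back to mean difference
    St = (1.0 - gamma) * S + gamma * nu * np.eye(d)
    try:
        w = np.linalg.solve(St, mu1 - mu2)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular shrunk covariance; use gamma > 0"
        ) from exc
    bias = float(-w @ (mu1 + mu2) / 2.0)
    return LinearModel(weights=w, bias=bias, kind="lda", gamma=float(gamma))


def train_linsvm(X: np.ndarray, y: np.ndarray, cost: float = 1.0) -> LinearModel:
    """Soft-margin linear SVM; deterministic for fixed data and cost."""
    X = np.asarray(X, dtype=float)
    _class_split(X, y)                # validates two classes present
    svc = SVC(kernel="linear", C=cost, tol=1e-6)
    svc.fit(X, np.asarray(y, dtype=str))
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    # sklearn's positive class is classes_[1]; flip so MA is positive
    if svc.classes_[1] != MA:
        w, b = -w, -b
    return LinearModel(weights=w, bias=b, kind="svm")


def _train(kind: str, X: np.ndarray, y: np.ndarray, cost: float = 1.0,
           gamma: Optional[float] = None) -> LinearModel:
    if kind == "lda":
        return train_slda(X, y, gamma=gamma)
    if kind == "svm":
        return train_linsvm(X, y, cost=cost)
    raise ConfigurationError(f"unknown classifier kind {kind!r}")


def train_meta(
    dv_a: np.ndarray,
    dv_b: np.ndarray,
    labels: np.ndarray,
    kind: str = "lda",
    cost: float = 1.0,
) -> LinearModel:
    """2-feature linear meta-classifier on base decision values."""
    dv_a = np.asarray(dv_a, dtype=float).ravel()
    dv_b = np.asarray(dv_b, dtype=float).ravel()
    labels = np.asarray(labels)
    if not (dv_a.shape == dv_b.shape == labels.shape):
        raise ProtocolError("base outputs and labels must cover the same trials")
    Z = np.column_stack([dv_a, dv_b])
    return _train(kind, Z, labels, cost=cost)


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold settings; splits are shared downstream."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    stratified: bool = True


def make_splits(
    labels: np.ndarray, scheme: CVScheme
) -> List[List[Tuple[np.ndarray, np.ndarray]]]:
    """Fold index pairs per repeat, deterministic in the scheme seed.

    Every trial appears in exactly one test fold per repeat and folds are
    class-balanced within +-1.
    """
    labels = np.asarray(labels, dtype=str)
    counts = pd.Series(labels).value_counts()
    if counts.min() < scheme.n_folds:
        raise ProtocolError(
            f"each class needs >= {scheme.n_folds} trials for {scheme.n_folds}-fold CV"
        )
    splits = []
    for rep in range(scheme.n_repeats):
        rep_seed = int(
            np.random.SeedSequence([scheme.seed, rep]).generate_state(1)[0] % 2**31
        )
        skf = StratifiedKFold(
            n_splits=scheme.n_folds, shuffle=True, random_state=rep_seed
        )
        splits.append(
            [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]
        )
    return splits


def splits_table(splits) -> pd.DataFrame:
    """Tidy serialization of the fold assignments (repeat, fold, trial)."""
    rows = []
    for rep, folds in enumerate(splits):
        for k, (_, test) in enumerate(folds):
            for t in test:
                rows.append((rep, k, int(t)))
    return pd.DataFrame(rows, columns=["repeat", "fold", "trial"])


@dataclass
class CVResult:
    """Per-fold accuracies and per-trial predictions of the CV protocol."""

    accuracies: pd.DataFrame          # anchor_s, repeat, fold, classifier, chromophores, accuracy_pct, n_test
    predictions: pd.DataFrame         # + trial, y_true, y_pred, decision_value
    scheme: CVScheme
    weight_hash: str = ""


def _inner_oof_decisions(
    Xtr_by_chromo: Dict[str, np.ndarray],
    ytr: np.ndarray,
    kind: str,
    cost: float,
    inner_folds: Optional[int],
    inner_seed: int,
) -> Dict[str, np.ndarray]:
    """Out-of-fold base decision values on the training trials.

    ``inner_folds=None`` selects the naive variant: bases trained on the
    full training set score their own training trials.
    """
    n = len(ytr)
    if inner_folds is None:
        return {
            c: _train(kind, X, ytr, cost=cost).decision(X)
            for c, X in Xtr_by_chromo.items()
        }
    oof = {c: np.empty(n) for c in Xtr_by_chromo}
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
    for itr, ite in skf.split(np.zeros(n), np.asarray(ytr, dtype=str)):
        for c, X in Xtr_by_chromo.items():
            model = _train(kind, X[itr], ytr[itr], cost=cost)
            oof[c][ite] = model.decision(X[ite])
    return oof


def crossvalidate(
    features_by_anchor: Dict[float, Dict[str, FeatureMatrix]],
    labels: np.ndarray,
    scheme: CVScheme,
    classifiers: Sequence[str] = CLASSIFIERS,
    chromo_sets: Sequence[str] = CHROMO_SETS,
    cost: float = 1.0,
    inner_folds: Optional[int] = 5,
    splits=None,
    collect_predictions: bool = True,
    corrupt_test_labels: Optional[np.random.Generator] = None,
) -> CVResult:
    """Repeated stratified CV over window anchors, classifiers and chromophores.

    ``features_by_anchor`` maps anchor -> {"hbo": FeatureMatrix, "hbr": ...}.
    Identical splits are reused everywhere; normalization and every model
    fit (including the meta inner loop) see training folds only.  The
    returned ``weight_hash`` digests all trained weights, enabling leakage
    audits: passing ``corrupt_test_labels`` (a Generator) randomizes the
    test-fold labels at scoring time only, which must leave the hash
    unchanged because no fit may ever see them.
    """
    labels = np.asarray(labels, dtype=object)
    if splits is None:
        splits = make_splits(labels, scheme)
    for cs in chromo_sets:
        if cs not in CHROMO_SETS:
            raise ConfigurationError(f"unknown chromophore set {cs!r}")
    single_needed = sorted(
        {cs for cs in chromo_sets if cs != "both"}
        | ({"hbo", "hbr"} if "both" in chromo_sets else set())
    )

    acc_rows: List[tuple] = []
    pred_rows: List[tuple] = []
    hasher = hashlib.sha256()

    for anchor in sorted(features_by_anchor):
        fms = features_by_anchor[anchor]
        for rep, folds in enumerate(splits):
            for k, (train_idx, test_idx) in enumerate(folds):
                ytr, yte = labels[train_idx], labels[test_idx]
                if corrupt_test_labels is not None:
                    yte = corrupt_test_labels.choice([MA, BL], size=len(test_idx)).astype(object)
                # leakage-safe normalization per chromophore
                Xtr, Xte = {}, {}
                for c in single_needed:
                    fm = fms[c]
                    fm_tr = FeatureMatrix(
                        X=fm.X[train_idx], labels=ytr, anchor=anchor, columns=fm.columns
                    )
                    norm = normalize_fit(fm_tr)
                    Xtr[c] = normalize_apply(norm, fm_tr).X
                    Xte[c] = (fm.X[test_idx] - norm.center) / norm.scale
                inner_seed = int(
                    np.random.SeedSequence([scheme.seed, rep, k, 7]).generate_state(1)[0]
                    % 2**31
                )
                for kind in classifiers:
                    base_models = {
                        c: _train(kind, Xtr[c], ytr, cost=cost) for c in single_needed
                    }
                    for model in base_models.values():
                        hasher.update(np.ascontiguousarray(model.weights).tobytes())
                    for cs in chromo_sets:
                        if cs == "both":
                            oof = _inner_oof_decisions(
                                Xtr, ytr, kind, cost, inner_folds, inner_seed
                            )
                            meta = train_meta(
                                oof["hbo"], oof["hbr"], ytr, kind=kind, cost=cost
                            )
                            hasher.update(np.ascontiguousarray(meta.weights).tobytes())
                            Zte = np.column_stack(
                                [
                                    base_models["hbo"].decision(Xte["hbo"]),
                                    base_models["hbr"].decision(Xte["hbr"]),
                                ]
                            )
                            dv = meta.decision(Zte)
                        else:
                            dv = base_models[cs].decision(Xte[cs])
                        pred = np.where(dv > 0, MA, BL).astype(object)
                        acc = 100.0 * float(np.mean(pred == yte))
                        acc_rows.append(
                            (anchor, rep, k, kind, cs, acc, len(test_idx))
                        )
                        if collect_predictions:
                            for j, t in enumerate(test_idx):
                                pred_rows.append(
                                    (anchor, rep, k, kind, cs, int(t),
                                     yte[j], pred[j], float(dv[j]))
                                )

    accuracies = pd.DataFrame(
        acc_rows,
        columns=["anchor_s", "repeat", "fold", "classifier", "chromophores",
                 "accuracy_pct", "n_test"],
    )
    predictions = pd.DataFrame(
        pred_rows,
        columns=["anchor_s", "repeat", "fold", "classifier", "chromophores",
                 "trial", "y_true", "y_pred", "decision_value"],
    )
    return CVResult(
        accuracies=accuracies,
        predictions=predictions,
        scheme=scheme,
        weight_hash=hasher.hexdigest(),
    )
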