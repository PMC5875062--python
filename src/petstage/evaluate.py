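"""Cross-validated evaluation: metrics, ROC/AUC, McNemar, pairwise runner.

Pairwise diagnostic experiments (e.g. AD vs NC) are scored with 10-fold
stratified cross-validation.  Fold predictions are pooled before computing
accuracy, sensitivity, specificity and AUC; the positive class is the more
cognitively impaired diagnosis of the pair.  Two classifiers on the same
samples are compared with McNemar's test on the discordant predictions,
using the exact binomial tail for fewer than 25 discordant pairs and the
continuity-corrected χ² approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, decision_scores, make_estimator
from .features import FeatureMatrix, concat_timepoints, mean_center

__all__ = [
    "MetricSet",
    "McNemarResult",
    "ExperimentSpec",
    "IMPAIRMENT_ORDER",
    "stratified_kfold",
    "confusion_metrics",
    "roc_auc",
    "mcnemar",
    "cross_validate",
    "run_pairwise_experiment",
]

# more impaired first
IMPAIRMENT_ORDER = ("AD", "LMCI", "EMCI", "NC")


def positive_class(pair: tuple[str, str]) -> str:
    """The more cognitively impaired member of a diagnostic pair."""
    ranked = sorted(pair, key=IMPAIRMENT_ORDER.index)
    return ranked[0]


@dataclass
class MetricSet:
    acc: float
    sen: float
    spe: float
    auc: float | None = None
    positive: str = ""


@dataclass
class McNemarResult:
    n01: int  # a correct, b wrong
    n10: int  # a wrong, b correct
    statistic: float
    p_value: float
    method: str  # exact_binomial | chi2_cc


@dataclass
class ExperimentSpec:
    pair: tuple[str, str] = ("AD", "NC")
    tracer: str = "FDG"
    timepoint_mode: str = "baseline"  # baseline | second | combined
    approach: str = "multiregion"  # multiregion | wholebrain
    classifiers: tuple[ClassifierSpec, ...] = ()
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("diagnostic pair must contain two distinct diagnoses")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")


def stratified_kfold(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index per sample; class proportions balanced within one sample."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    smallest = np.min(np.bincount(np.unique(y, return_inverse=True)[1]))
    if smallest < k:
        warnings.warn(f"reducing folds from {k} to {smallest} (smallest class size)")
        k = int(smallest)
        if k < 2:
            raise ValueError("smallest class has fewer than 2 samples")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(y.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((y.shape[0], 1)), y)):
        folds[test_idx] = fold
    return folds


def confusion_metrics(y_true, y_pred, positive) -> MetricSet:
    """ACC, SEN, SPE from the binary confusion table."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_true = y_true == positive
    pos_pred = y_pred == positive
    tp = int(np.sum(pos_true & pos_pred))
    fn = int(np.sum(pos_true & ~pos_pred))
    tn = int(np.sum(~pos_true & ~pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    if np.isnan(sen) or np.isnan(spe):
        warnings.warn("a class is absent from y_true; SEN or SPE is undefined")
    return MetricSet(acc=acc, sen=sen, spe=spe, positive=str(positive))


def roc_auc(scores, y_true, positive) -> tuple[np.ndarray, float]:
    """ROC points from a threshold sweep and the pairwise-probability AUC.

    AUC = P(score_pos > score_neg) + ½ P(tie) over all positive/negative
    pairs, which equals the trapezoidal area under the threshold-sweep ROC.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = scores[y_true == positive]
    neg = scores[y_true != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    # pairwise definition via rank statistics (equivalent to brute force)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = []
    for thr in thresholds:
        pred_pos = scores >= thr
        tpr = np.mean(pred_pos[y_true == positive])
        fpr = np.mean(pred_pos[y_true != positive])
        points.append((fpr, tpr))
    return np.asarray(points), float(auc)


def mcnemar(pred_a, pred_b, y_true) -> McNemarResult:
    """Paired comparison of two classifiers on identical samples."""
    pred_a, pred_b, y_true = map(np.asarray, (pred_a, pred_b, y_true))
    if not (pred_a.shape == pred_b.shape == y_true.shape):
        raise ValueError("predictions and truth must have identical lengths")
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    n01 = int(np.sum(a_ok & ~b_ok))
    n10 = int(np.sum(~a_ok & b_ok))
    n = n01 + n10
    if n < 25:
        k = min(n01, n10)
        p = min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)) if n > 0 else 1.0
        return McNemarResult(n01, n10, statistic=float(k), p_value=float(p), method="exact_binomial")
    chi2 = (abs(n01 - n10) - 1) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(n01, n10, statistic=float(chi2), p_value=p, method="chi2_cc")


def cross_validate(
    spec: ClassifierSpec,
    X: FeatureMatrix,
    y: np.ndarray,
    positive: str,
    folds: int = 10,
    seed: int = 0,
    center: bool = True,
) -> dict:
    """Pooled-fold CV predictions and scores for one classifier.

    Mean-centering is re-fit on the training rows of each fold before
    predicting the held-out rows.
    """
    y = np.asarray(y)
    fold_idx = stratified_kfold(y, k=folds, seed=seed)
    y_pred = np.empty(y.shape, dtype=y.dtype)
    y_score = np.empty(y.shape[0], dtype=float)
    for fold in np.unique(fold_idx):
        test = fold_idx == fold
        train_rows = np.flatnonzero(~test)
        Xc = mean_center(X, fit_rows=train_rows) if center else X
        model = make_estimator(spec)
        model.fit(Xc.X[train_rows], y[train_rows])
        scores = decision_scores(model, Xc.X[test])
        if list(model.classes_)[-1] != positive:
            scores = -scores
        y_pred[test] = model.predict(Xc.X[test])
        y_score[test] = scores
    metrics = confusion_metrics(y, y_pred, positive)
    _, auc = roc_auc(y_score, y, positive)
    metrics.auc = auc
    return {"metrics": metrics, "y_pred": y_pred, "y_score": y_score, "folds": fold_idx}


def run_pairwise_experiment(
    features_by_timepoint: dict[str, FeatureMatrix],
    diagnoses: np.ndarray,
    spec: ExperimentSpec,
) -> pd.DataFrame:
    """Evaluate each classifier of `spec` on one diagnostic pair.

    `features_by_timepoint` maps "baseline" and optionally "second_visit"
    to feature matrices whose rows cover the full cohort in the same
    order as `diagnoses`.  Returns one tidy row per classifier with
    ACC/SEN/SPE/AUC from pooled 10-fold CV predictions; the prediction
    vectors are attached in the `predictions` column for McNemar
    comparisons downstream.
    """
    diagnoses = np.asarray(diagnoses)
    keep = np.isin(diagnoses, list(spec.pair))
    if keep.sum() < 2 * spec.folds:
        counts = {d: int(np.sum(diagnoses == d)) for d in spec.pair}
        raise ValueError(f"not enough subjects for {spec.folds}-fold CV: {counts}")

    if spec.timepoint_mode == "baseline":
        X_full = features_by_timepoint["baseline"]
    elif spec.timepoint_mode == "second":
        X_full = features_by_timepoint["second_visit"]
    elif spec.timepoint_mode == "combined":
        X_full = concat_timepoints(features_by_timepoint["baseline"], features_by_timepoint["second_visit"])
    else:
        raise ValueError(f"unknown timepoint mode {spec.timepoint_mode!r}")

    X = FeatureMatrix(
        X=X_full.X[keep],
        subjects=[s for s, k in zip(X_full.subjects, keep) if k],
        block_map=dict(X_full.block_map),
    )
    y = diagnoses[keep]
    pos = positive_class(spec.pair)

    rows = []
    for clf in spec.classifiers:
        result = cross_validate(clf, X, y, positive=pos, folds=spec.folds, seed=spec.seed)
        m = result["metrics"]
        rows.append(
            {
                "pair": f"{spec.pair[0]}_vs_{spec.pair[1]}",
                "tracer": spec.tracer,
                "timepoints": spec.timepoint_mode,
                "classifier": clf.variant,
                "acc": m.acc,
                "sen": m.sen,
                "spe": m.spe,
                "auc": m.auc,
                "positive": pos,
                "width": X.width,
                "predictions": result["y_pred"],
                "y_true": y,
            }
        )
    return pd.DataFrame(rows)
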