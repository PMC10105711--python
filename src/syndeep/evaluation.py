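"""Cross-validation harness, confusion-matrix metric suite, ROC/AUC,
McNemar's paired test, and the six-group feature ablation.

Metrics follow the standard confusion-matrix definitions: accuracy,
sensitivity (recall on the synergistic class), specificity, precision,
F-score, the Matthews correlation coefficient and Cohen's kappa with chance
agreement computed from the marginals. AUC is the rank (Mann-Whitney)
statistic — the probability that a random positive outscores a random
negative, ties counted one half. McNemar's test uses the continuity
corrected statistic (|B - C| - 1)^2 / (B + C) on the discordant pairs, with
a chi-squared null on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.model_selection import StratifiedKFold

from .featnet import FeatureSchema, build_design_matrix
from .labels import PairRecord
from .models import ModelSpec, predict_label, predict_proba, train
from .universe import RelationalUniverse

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "McNemarResult",
    "CVResult",
    "confusion_from_predictions",
    "stratified_kfold",
    "compute_metrics",
    "roc_auc",
    "mcnemar",
    "cross_validate",
    "ablation_report",
    "ablation_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "f_score", "mcc", "kappa", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    mcc: float
    kappa: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class McNemarResult:
    """Discordant counts and the continuity-corrected chi-squared statistic.

    B counts samples the first classifier got right and the second wrong; C
    the reverse. With no discordant pairs the statistic is undefined and
    ``applicable`` is False.
    """

    b: int
    c: int
    statistic: float
    p_value: float
    applicable: bool


@dataclass
class CVResult:
    """Per-fold metric reports, their mean, and pooled predictions."""

    per_fold: list[MetricsReport]
    mean: MetricsReport
    pooled_labels: np.ndarray      # true labels, record order
    pooled_predictions: np.ndarray  # hard labels, record order
    pooled_scores: np.ndarray       # probabilities, record order
    fold_assignment: np.ndarray

    @property
    def pooled_metrics(self) -> MetricsReport:
        report = compute_metrics(
            confusion_from_predictions(self.pooled_labels, self.pooled_predictions)
        )
        report.auc = roc_auc(self.pooled_scores, self.pooled_labels)
        return report


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each record to one of k class-stratified folds (seeded).

    Fold sizes differ by at most one, per-fold class counts are within one
    of proportionality, and each record lands in exactly one test fold.
    """
    y = np.asarray(labels)
    if k > y.size:
        raise ValueError(f"k={k} exceeds the number of records ({y.size})")
    counts = np.unique(y, return_counts=True)[1]
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minimum class count ({counts.min()}); "
            "folds could not be stratified"
        )
    assignment = np.empty(y.size, dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(y.size), y)):
        assignment[test_idx] = fold
    return assignment


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the confusion-derived metric suite (AUC set separately).

    MCC is defined as 0 whenever a marginal under the root is 0; kappa's
    chance agreement P_c is the usual two-rater product of marginal rates.
    Ratio metrics with an empty denominator are reported as 0.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    n = c.n
    if n == 0:
        raise ValueError("confusion table is empty")
    accuracy = (tp + tn) / n
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    f_score = _safe_div(2 * sensitivity * precision, sensitivity + precision)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den != 0 else 0.0
    p_c = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _safe_div(accuracy - p_c, 1 - p_c)
    return MetricsReport(accuracy, sensitivity, specificity, precision,
                         f_score, float(mcc), kappa)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney rank statistic.

    Equals the probability that a uniformly chosen positive receives a
    higher score than a uniformly chosen negative, counting ties as 1/2 —
    identical to trapezoidal integration over all thresholds, but exact and
    threshold-free.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def mcnemar(predictions_a, predictions_b, labels) -> McNemarResult:
    """McNemar's test on the discordant cells of two paired classifiers.

    B = first correct, second wrong; C = first wrong, second correct.
    Statistic: (|B - C| - 1)^2 / (B + C), chi-squared with 1 df.
    """
    a = np.asarray(predictions_a)
    b = np.asarray(predictions_b)
    y = np.asarray(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("prediction and label vectors must share one length")
    a_correct = a == y
    b_correct = b == y
    B = int(np.sum(a_correct & ~b_correct))
    C = int(np.sum(~a_correct & b_correct))
    if B + C == 0:
        return McNemarResult(0, 0, float("nan"), float("nan"), applicable=False)
    stat = (abs(B - C) - 1) ** 2 / (B + C)
    return McNemarResult(B, C, stat, float(chi2.sf(stat, df=1)), applicable=True)


def _fold_report(y_true, y_pred, scores) -> MetricsReport:
    report = compute_metrics(confusion_from_predictions(y_true, y_pred))
    report.auc = roc_auc(scores, y_true)
    return report


def cross_validate(
    spec: ModelSpec,
    records: list[PairRecord],
    universe: RelationalUniverse,
    group: int,
    k: int = 10,
    seed: int = 0,
    schema: FeatureSchema | None = None,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """k-fold cross-validation of one model spec on one feature group.

    Scaling and fitting see only the training fold (train() fits its scaler
    on the rows it is given); the report aggregates fold metrics by mean and
    keeps pooled predictions for paired comparisons.
    """
    X, y = build_design_matrix(universe, records, group, schema=schema)
    return _cross_validate_xy(spec, X, y, k=k, seed=seed,
                              fold_assignment=fold_assignment)


def _cross_validate_xy(spec, X, y, k=10, seed=0, fold_assignment=None) -> CVResult:
    if fold_assignment is None:
        fold_assignment = stratified_kfold(y, k=k, seed=seed)
    folds = np.unique(fold_assignment)
    pooled_pred = np.empty(y.size, dtype=int)
    pooled_score = np.empty(y.size, dtype=float)
    per_fold = []
    for fold in folds:
        test = fold_assignment == fold
        model = train(spec, X[~test], y[~test], seed=seed + int(fold))
        scores = predict_proba(model, X[test])
        preds = (scores >= 0.5).astype(int)
        pooled_score[test] = scores
        pooled_pred[test] = preds
        per_fold.append(_fold_report(y[test], preds, scores))
    mean = MetricsReport(**{
        name: float(np.mean([getattr(r, name) for r in per_fold]))
        for name in METRIC_NAMES
    })
    return CVResult(per_fold, mean, y.copy(), pooled_pred, pooled_score,
                    fold_assignment)


def ablation_report(
    records: list[PairRecord],
    universe: RelationalUniverse,
    spec: ModelSpec,
    seed: int = 0,
    k: int = 10,
    groups=(1, 2, 3, 4, 5, 6),
    schema: FeatureSchema | None = None,
) -> dict[int, CVResult]:
    """Cross-validate one model over the cumulative feature groups.

    The same fold assignment is reused across groups so per-fold metrics are
    paired and group differences are not confounded by the partition.
    """
    schema = schema or FeatureSchema.from_universe(universe)
    y = np.asarray([r.label for r in records])
    fold_assignment = stratified_kfold(y, k=k, seed=seed)
    return {
        g: cross_validate(spec, records, universe, g, k=k, seed=seed,
                          schema=schema, fold_assignment=fold_assignment)
        for g in groups
    }


def ablation_table(report: dict[int, CVResult]) -> pd.DataFrame:
    """Mean metrics, one row per feature group, one column per metric."""
    rows = {g: r.mean.as_dict() for g, r in sorted(report.items())}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))
    df.index.name = "group"
    return df
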