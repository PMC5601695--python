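"""SVM subtype classification on pathway-score features.

Classifier settings mirror the fixed, non-tuned configuration the analysis
prescribes: RBF kernel, C = 1, and the legacy "gamma = 0" sentinel resolved
to 1 / n_features (an RBF gamma must be positive).  Evaluation is
stratified five-fold cross-validation: every sample is predicted exactly
once by a model never trained on it, and the pooled cross-validated
decision scores feed the ROC curve.

Two entry points:

* a four-class model over all subtypes (confusion matrix + per-class
  precision/recall/F1);
* three pairwise models (LA/LB, LA/TN, LB/TN) — HER2+ is excluded from the
  pairwise analysis because its support is too small — whose features are
  the pathways significantly enriched for either subtype's specific genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .enrichment import fisher_enrichment
from .exceptions import InputError
from .io import ExpressionMatrix, GeneSetCollection
from .pathway_score import PathwayScoreMatrix, reference_means, score_matrix
from .screen import GeneScreenResult

logger = logging.getLogger(__name__)

PAIRS: tuple[tuple[str, str], ...] = (("LA", "LB"), ("LA", "TN"), ("LB", "TN"))


@dataclass
class ClassifierSpec:
    """Fixed SVM configuration; ``gamma=None`` means 1 / n_features."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InputError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise InputError("gamma must be positive once the sentinel is resolved")

    def make_svc(self) -> SVC:
        return SVC(
            C=self.C,
            kernel=self.kernel,
            gamma=self.gamma if self.gamma is not None else "auto",
            random_state=self.seed,
        )


@dataclass
class ClassificationReport:
    classes: list[str]
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    per_class: dict[str, dict[str, float]]
    averages: dict[str, float]
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    zero_division_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": [
                [round(v, 10) for v in row] for row in self.confusion_normalized
            ],
            "per_class": {
                c: {k: round(v, 10) for k, v in m.items()}
                for c, m in self.per_class.items()
            },
            "averages": {k: round(v, 10) for k, v in self.averages.items()},
            "auc": None if self.auc is None else round(self.auc, 10),
        }


def five_fold_cv_predict(
    features: PathwayScoreMatrix | np.ndarray,
    labels: dict[str, str] | list[str],
    spec: ClassifierSpec,
) -> dict[str, tuple[str, float]]:
    """Stratified 5-fold cross-validated prediction for every sample.

    Returns sample -> (predicted class, decision score).  For binary
    problems the score is the signed distance for the positive
    (lexicographically later) class; for multiclass it is the one-vs-rest
    margin of the predicted class.
    """
    if isinstance(features, PathwayScoreMatrix):
        x = features.scores
        sample_ids = features.samples
    else:
        x = np.asarray(features, dtype=float)
        sample_ids = [f"s{i}" for i in range(x.shape[0])]
    if isinstance(labels, dict):
        y = np.array([labels[s] for s in sample_ids])
    else:
        y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("need at least two classes")
    small = [str(c) for c, n in zip(classes, counts) if n < 5]
    if small:
        raise InputError(
            f"classes with <5 samples cannot be 5-fold stratified: {small}; "
            "merge or drop them (the pairwise analysis drops HER2+)"
        )
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed)
    out: dict[str, tuple[str, float]] = {}
    for train_idx, test_idx in skf.split(x, y):
        clf = spec.make_svc()
        clf.fit(x[train_idx], y[train_idx])
        pred = clf.predict(x[test_idx])
        dec = clf.decision_function(x[test_idx])
        for k, idx in enumerate(test_idx):
            if dec.ndim == 1:
                score = float(dec[k])
            else:
                cls_idx = list(clf.classes_).index(pred[k])
                score = float(dec[k, cls_idx])
            out[sample_ids[idx]] = (str(pred[k]), score)
    return out


def confusion_matrix(
    actual, predicted, classes: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Counts (actual rows x predicted columns) and row-normalized rates."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise InputError("actual and predicted lengths differ")
    if classes is None:
        classes = sorted(set(actual))
    index = {c: i for i, c in enumerate(classes)}
    bad = [v for v in set(actual) | set(predicted) if v not in index]
    if bad:
        raise InputError(f"labels outside the class set: {bad}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, 0.0)
    return counts, norm, list(classes)


def report_metrics(
    confusion: np.ndarray, classes: list[str]
) -> tuple[dict[str, dict[str, float]], dict[str, float], list[str]]:
    """Per-class precision/recall/F1/support and support-weighted averages.

    Division-by-zero cells (class never predicted, or empty class) are
    reported as 0 and flagged.
    """
    confusion = np.asarray(confusion)
    if confusion.size == 0:
        raise InputError("empty confusion matrix")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    supports = confusion.sum(axis=1)
    predicted_totals = confusion.sum(axis=0)
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        if predicted_totals[i] == 0:
            precision = 0.0
            flags.append(f"precision[{c}]")
        else:
            precision = tp / predicted_totals[i]
        if supports[i] == 0:
            recall = 0.0
            flags.append(f"recall[{c}]")
        else:
            recall = tp / supports[i]
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        per_class[c] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "support": int(supports[i]),
        }
    total = supports.sum()
    averages = {
        key: float(sum(per_class[c][key] * per_class[c]["support"] for c in classes) / total)
        for key in ("precision", "recall", "f1")
    }
    averages["support"] = int(total)
    return per_class, averages, flags


def roc_auc(scores, binary_labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points from a threshold sweep and the trapezoid AUC.

    The trapezoid AUC over the tie-aware ROC equals the normalized
    Mann-Whitney U statistic (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=bool)
    if y.all() or not y.any():
        raise InputError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep one point per distinct threshold (last occurrence)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / y.sum()]
    fpr = np.r_[0.0, fps[distinct] / (~y).sum()]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def build_report(
    predictions: dict[str, tuple[str, float]],
    labels: dict[str, str],
    classes: list[str],
    positive_class: str | None = None,
) -> ClassificationReport:
    """Assemble confusion, metrics and (for binary problems) ROC/AUC."""
    samples = list(predictions)
    actual = [labels[s] for s in samples]
    predicted = [predictions[s][0] for s in samples]
    counts, norm, classes = confusion_matrix(actual, predicted, classes)
    per_class, averages, flags = report_metrics(counts, classes)
    roc = None
    auc = None
    if len(classes) == 2:
        pos = positive_class if positive_class is not None else classes[-1]
        decision = np.array([predictions[s][1] for s in samples])
        is_pos = np.array([a == pos for a in actual])
        # decision scores are signed toward the lexicographically later class
        if pos == sorted(classes)[0]:
            decision = -decision
        roc, auc = roc_auc(decision, is_pos)
    return ClassificationReport(
        classes=classes,
        confusion=counts,
        confusion_normalized=norm,
        per_class=per_class,
        averages=averages,
        roc=roc,
        auc=auc,
        zero_division_flags=flags,
    )


def fourclass_model(
    scores: PathwayScoreMatrix, labels: dict[str, str], spec: ClassifierSpec
) -> ClassificationReport:
    """Four-class SVM on a (column-standardized) pathway score matrix."""
    features = scores if scores.zscored else scores.zscore_columns()
    predictions = five_fold_cv_predict(features, labels, spec)
    classes = sorted({labels[s] for s in scores.samples})
    return build_report(predictions, labels, classes)


def pairwise_models(
    expr: ExpressionMatrix,
    screen_result: GeneScreenResult,
    collection: GeneSetCollection,
    spec: ClassifierSpec,
    enrich_alpha: float = 0.05,
    epsilon: float = 1e-6,
    pairs: tuple[tuple[str, str], ...] = PAIRS,
) -> dict[tuple[str, str], ClassificationReport]:
    """One binary SVM per subtype pair on pair-enriched pathway features.

    For each pair, the feature pathways are those significantly enriched
    (P < ``enrich_alpha``) for either subtype's specific gene set; scores
    are computed against the full-cohort LA reference, restricted to the
    pair's samples and column-standardized.
    """
    enriched: dict[str, list[str]] = {}
    for subtype in {s for pair in pairs for s in pair}:
        rows = fisher_enrichment(
            screen_result.specific_sets[subtype], collection, alpha=enrich_alpha
        )
        enriched[subtype] = [r.pathway for r in rows if r.significant]
    mu, _ = reference_means(expr, epsilon)
    reports: dict[tuple[str, str], ClassificationReport] = {}
    for a, b in pairs:
        pathways = sorted(set(enriched[a]) | set(enriched[b]))
        if not pathways:
            raise InputError(
                f"no pathway enriched for {a} or {b} specific genes at "
                f"alpha={enrich_alpha}; cannot build the {a}/{b} model"
            )
        logger.info("%s/%s model uses %d pathways", a, b, len(pathways))
        pair_samples = [s for s in expr.samples if expr.labels[s] in (a, b)]
        sub_expr = expr.subset_samples(pair_samples)
        scores = score_matrix(
            sub_expr, collection, pathways=pathways, epsilon=epsilon, mu=mu,
            zscore_columns=True,
        )
        predictions = five_fold_cv_predict(scores, expr.labels, spec)
        reports[(a, b)] = build_report(
            predictions, expr.labels, sorted((a, b)),
            positive_class=max((a, b), key=lambda s: ["LA", "LB", "HER2+", "TN"].index(s)),
        )
    return reports
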