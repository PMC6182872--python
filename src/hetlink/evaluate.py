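"""Dataset construction, stratified cross-validation and performance metrics.

Supervised sets pair known interactions (positives) with uniformly
sampled non-interacting pairs (negatives) at configurable ratios
(1:1, 1:2, 1:5, 1:10).  Performance is summarized by the confusion
matrix at a 0.5 score threshold (precision, recall/sensitivity,
specificity, accuracy, F-measure, MCC) and by the threshold-free AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .hetnet import NodeRegistry, PROTEIN, LNCRNA
from .model import FeatureSchema, GTBParams, predict, train_gtb


class MetricError(ValueError):
    """Metrics requested on empty or malformed input."""


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    specificity: float
    accuracy: float
    f_measure: float
    mcc: float
    auc: float

    def as_dict(self) -> dict:
        return asdict(self)


def sample_negatives(
    known_positives: set[tuple[str, str]] | list[tuple[str, str]],
    registry: NodeRegistry,
    count: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform sample of (protein, lncRNA) pairs outside the known set."""
    known = set(known_positives)
    prots = [nid for nid in registry.ids if registry.node_type[nid] == PROTEIN]
    lncs = [nid for nid in registry.ids if registry.node_type[nid] == LNCRNA]
    candidates = [(p, l) for p in prots for l in lncs if (p, l) not in known]
    if count > len(candidates):
        raise ValueError(
            f"requested {count} negatives but only {len(candidates)} "
            f"non-interacting pairs exist"
        )
    if count == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return [candidates[k] for k in chosen]


def kfold_split(
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> list[np.ndarray]:
    """Index folds of roughly equal size, stratified by label by default."""
    labels = np.asarray(labels)
    if k > len(labels):
        raise ValueError("more folds than samples")
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    """Confusion-matrix measures at the threshold, plus rank-based AUC."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise MetricError("no samples to evaluate")
    if labels.shape != scores.shape:
        raise MetricError("labels and scores length mismatch")
    if scores.min() < 0 or scores.max() > 1:
        raise MetricError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    specificity = _safe_div(tn, tn + fp, "specificity")
    accuracy = (tp + tn) / labels.size
    f_measure = _safe_div(2 * precision * recall, precision + recall, "F-measure")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels; AUC undefined, reporting 0", stacklevel=2)
        auc = 0.0
    else:
        auc = float(roc_auc_score(labels, scores))  # midrank handling of ties
    return MetricsReport(tp, fp, tn, fn, precision, recall, specificity,
                         accuracy, f_measure, mcc, auc)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    schema: FeatureSchema,
    params: GTBParams | None = None,
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[dict, list[MetricsReport]]:
    """k-fold CV of the boosted-tree model; metrics on held-out folds only.

    Returns (summary, per-fold reports) where summary maps each metric
    to its mean and standard deviation over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = kfold_split(y, k=k, seed=seed, stratify=stratify)
    all_idx = np.arange(len(y))
    reports: list[MetricsReport] = []
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        assert not set(train_idx) & set(test_idx)
        model = train_gtb(X[train_idx], y[train_idx], schema, params, seed=seed)
        scores = predict(model, X[test_idx])
        reports.append(compute_metrics(y[test_idx], scores))
    summary: dict = {}
    for key in ("precision", "recall", "specificity", "accuracy",
                "f_measure", "mcc", "auc"):
        vals = np.array([getattr(r, key) for r in reports])
        summary[key] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return summary, reports
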