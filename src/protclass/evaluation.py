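"""Resampling protocols and the metric suite.

Balanced sample sets (all positives plus an equal-size random draw of
negatives), stratified k-fold cross-validation, leave-one-out CV, the
confusion-count metrics Sn/Sp/Ac/Pre/MCC and the trapezoidal AUC-ROC.

A metric whose denominator is zero is *undefined*: it is reported as NaN,
excluded from aggregation and counted, never coerced to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import KernelSpec, predict, train_svm
from .descriptors import Encoder
from .seqio import LabeledDataset, ProteinRecord

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Sn", "Sp", "Ac", "Pre", "MCC", "AUC")


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """tp/tn/fp/fn with +1 the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, Ac, Pre and MCC from confusion counts.

    Sn = tp/(tp+fn); Sp = tn/(tn+fp); Ac = (tp+tn)/total;
    Pre = tp/(tp+fp); MCC = (tp*tn - fp*fn) / sqrt of the four
    marginal products.  Zero denominators yield NaN (undefined).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    mcc_den = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    return {
        "Sn": ratio(tp, tp + fn),
        "Sp": ratio(tn, tn + fp),
        "Ac": ratio(tp + tn, counts.total),
        "Pre": ratio(tp, tp + fp),
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep from (0,0) to (1,1); both coordinates non-decreasing."""

    fpr: np.ndarray  # alpha
    tpr: np.ndarray  # 1 - beta
    thresholds: np.ndarray


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Build the ROC curve over all distinct score thresholds.

    Instances scoring >= threshold are called positive; tied scores are
    grouped at a single threshold so the curve is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (y[order] == 1).astype(int)
    cum_tp = np.cumsum(sorted_pos)
    cum_fp = np.cumsum(1 - sorted_pos)
    # keep the last instance of each tied score group
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, cum_tp[distinct] / n_pos]
    fpr = np.r_[0.0, cum_fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve.

    Accumulates sum_i [ (1-beta)_{i-1} * d_alpha + (1/2) * d(1-beta) * d_alpha ]
    over consecutive sweep points; equals the Mann-Whitney estimate of
    P(score+ > score-) with ties counted one half.
    """
    curve = roc_curve(scores, labels)
    d_alpha = np.diff(curve.fpr)
    d_tpr = np.diff(curve.tpr)
    return float(np.sum(curve.tpr[:-1] * d_alpha + 0.5 * d_tpr * d_alpha))


# ---------------------------------------------------------------------------
# resampling protocols
# ---------------------------------------------------------------------------

def balanced_sample_sets(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    n_sets: int,
    seed: int,
) -> list[LabeledDataset]:
    """Balanced datasets: all positives plus an equal-size negative draw.

    Draws are without replacement within a set and independent across
    sets; reproducible given ``seed``.
    """
    positives, negatives = list(positives), list(negatives)
    if len(negatives) < len(positives):
        raise ValueError(
            f"need at least as many negatives ({len(negatives)}) "
            f"as positives ({len(positives)})"
        )
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        draw = rng.choice(len(negatives), size=len(positives), replace=False)
        sets.append(
            LabeledDataset.from_classes(positives, [negatives[i] for i in draw])
        )
    return sets


def kfold_split(
    n: int,
    k: int,
    seed: int,
    stratified: bool = False,
    labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """k disjoint index groups covering 0..n-1, sizes differing by <= 1.

    Stratified mode deals each class's shuffled indices round-robin with a
    counter continuing across classes, preserving the class ratio per fold
    within one instance while keeping fold sizes within one overall.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, k)]
    if labels is None:
        raise ValueError("stratified split requires labels")
    y = np.asarray(labels)
    if y.shape != (n,):
        raise ValueError("labels must have length n")
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0
    for cls in np.unique(y):
        cls_idx = rng.permutation(np.flatnonzero(y == cls))
        for i in cls_idx:
            folds[counter % k].append(int(i))
            counter += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one train/test split."""

    counts: ConfusionCounts
    metrics: dict[str, float]
    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    scores: np.ndarray
    y_true: np.ndarray


def _evaluate_split(
    features, y, train_idx, test_idx, kernel, c, seed, probability
) -> FoldResult:
    model = train_svm(
        features.subset(train_idx), y[train_idx], kernel, c,
        probability=probability, seed=seed,
    )
    test_features = features.subset(test_idx)
    pred = predict(model, test_features)
    scores = (
        pred.probabilities if pred.probabilities is not None else pred.decision_values
    )
    counts = ConfusionCounts.from_predictions(y[test_idx], pred.labels)
    metrics = compute_metrics(counts)
    try:
        metrics["AUC"] = auc_roc(scores, y[test_idx])
    except ValueError:  # single-class test fold
        metrics["AUC"] = math.nan
    return FoldResult(
        counts=counts,
        metrics=metrics,
        test_ids=test_features.ids,
        train_ids=features.subset(train_idx).ids,
        scores=np.asarray(scores, dtype=float),
        y_true=y[test_idx],
    )


def run_cv(
    dataset: LabeledDataset,
    encoder: Encoder,
    kernel: KernelSpec = KernelSpec("rbf"),
    c: float = 1.0,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    probability: bool = False,
) -> list[FoldResult]:
    """k-fold cross-validation on one (balanced) dataset.

    Sequences are encoded once (encoding is per-sequence, so there is no
    train/test leakage); each fold trains on the other k-1 folds and
    scores the held-out fold.  ROC scores are calibrated probabilities
    when ``probability`` is on, decision values otherwise.
    """
    y = dataset.labels
    features = encoder.transform(dataset.records)
    folds = kfold_split(len(dataset), k, seed=seed, stratified=stratified, labels=y)
    results = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        results.append(
            _evaluate_split(features, y, train_idx, test_idx, kernel, c, seed, probability)
        )
    return results


@dataclass(frozen=True)
class LoocvResult:
    """Per-instance predictions plus pooled counts and metrics."""

    ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    counts: ConfusionCounts
    metrics: dict[str, float]


def run_loocv(
    dataset: LabeledDataset,
    encoder: Encoder,
    kernel: KernelSpec = KernelSpec("rbf"),
    c: float = 1.0,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-out CV: each instance scored by a model trained on the rest.

    Metrics are computed on the pooled confusion counts; AUC on the pooled
    decision values.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 instances")
    y = dataset.labels
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("LOOCV requires both classes")
    features = encoder.transform(dataset.records)
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        train_idx = np.r_[0:i, i + 1 : n]
        if len(set(y[train_idx])) < 2:
            raise ValueError(
                f"leaving out instance {dataset.records[i].id!r} empties a class"
            )
        model = train_svm(
            features.subset(train_idx), y[train_idx], kernel, c,
            probability=False, seed=seed,
        )
        p = predict(model, features.subset([i]))
        preds[i] = p.labels[0]
        scores[i] = p.decision_values[0]
    counts = ConfusionCounts.from_predictions(y, preds)
    metrics = compute_metrics(counts)
    metrics["AUC"] = auc_roc(scores, y)
    return LoocvResult(
        ids=tuple(dataset.ids), y_true=y, y_pred=preds, scores=scores,
        counts=counts, metrics=metrics,
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-cell metric values with mean +/- sd aggregation.

    ``cells`` is a tidy frame with columns (sample_set, fold, metric,
    value); NaN cells are undefined metrics, excluded from aggregation and
    counted.  The headline sd is the sample sd over all defined cells; the
    sd over per-set means is also provided.
    """

    cells: pd.DataFrame
    protocol: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in METRIC_NAMES:
            vals = self.cells.loc[self.cells["metric"] == metric, "value"]
            defined = vals.dropna()
            if defined.empty:
                raise ValueError(f"metric {metric} is undefined in every cell")
            set_means = (
                self.cells.loc[self.cells["metric"] == metric]
                .groupby("sample_set")["value"]
                .mean()
            )
            rows.append(
                {
                    "metric": metric,
                    "mean": float(defined.mean()),
                    "sd": float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
                    "sd_over_set_means": (
                        float(set_means.std(ddof=1)) if len(set_means) > 1 else 0.0
                    ),
                    "n_defined": int(len(defined)),
                    "n_undefined": int(vals.isna().sum()),
                }
            )
        return pd.DataFrame(rows).set_index("metric")

    @property
    def n_cells_per_metric(self) -> int:
        return int((self.cells["metric"] == METRIC_NAMES[0]).sum())

    def to_csv(self, full_path: str | Path, summary_path: str | Path) -> None:
        self.cells.to_csv(full_path, index=False)
        self.summary().to_csv(summary_path)


def aggregate_report(
    per_set_results: Sequence[Sequence[dict[str, float]]],
    protocol: dict | None = None,
) -> EvaluationReport:
    """Assemble fold-level metric dicts (grouped by sample set) into a report."""
    rows = []
    n_undefined = 0
    for set_i, fold_metrics in enumerate(per_set_results):
        for fold_i, metrics in enumerate(fold_metrics):
            for metric in METRIC_NAMES:
                value = metrics.get(metric, math.nan)
                if isinstance(value, float) and math.isnan(value):
                    n_undefined += 1
                rows.append(
                    {
                        "sample_set": set_i,
                        "fold": fold_i,
                        "metric": metric,
                        "value": value,
                    }
                )
    if n_undefined:
        logger.info("aggregate_report: %d undefined metric cell(s)", n_undefined)
    return EvaluationReport(cells=pd.DataFrame(rows), protocol=protocol or {})


def evaluate_balanced(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    encoder: Encoder,
    kernel: KernelSpec = KernelSpec("rbf"),
    c: float = 1.0,
    n_sets: int = 100,
    k: int = 10,
    seed: int = 0,
    loocv: bool = False,
    stratified: bool = True,
    probability: bool = False,
) -> EvaluationReport:
    """Full protocol: balanced sample sets, then k-fold CV (or LOOCV) per set."""
    sets = balanced_sample_sets(positives, negatives, n_sets, seed)
    per_set: list[list[dict[str, float]]] = []
    for set_i, dataset in enumerate(sets):
        if loocv:
            result = run_loocv(dataset, encoder, kernel, c, seed=seed + set_i)
            per_set.append([result.metrics])
        else:
            folds = run_cv(
                dataset, encoder, kernel, c, k=k, seed=seed + set_i,
                stratified=stratified, probability=probability,
            )
            per_set.append([f.metrics for f in folds])
    protocol = {
        "n_sets": n_sets,
        "k": None if loocv else k,
        "loocv": loocv,
        "seed": seed,
        "scheme": encoder.scheme,
        "kernel": kernel.kind,
        "c": c,
    }
    return aggregate_report(per_set, protocol)
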