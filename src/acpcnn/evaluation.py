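"""Metrics, stratified cross-validation, independent testing, and the
seven-way representation-combination sweep.

The metric suite is the standard binary-classification set reported for
peptide predictors: accuracy, sensitivity, specificity and precision on the
0-100 percent scale, the Matthews correlation coefficient in [-1, 1], and
ROC/AUC from the positive-class scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .encoders import COMBINATIONS, DatasetEncoder, resolve_combination
from .io import Dataset
from .model import MHCNN, ModelConfig, build_mhcnn, predict_label

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    """Percent-scale accuracy/sensitivity/specificity/precision, MCC, AUC."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    counts: ConfusionCounts
    auc: Optional[float] = None

    def as_dict(self, decimals: Optional[int] = None) -> dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        if self.auc is not None:
            d["auc"] = self.auc
        if decimals is not None:
            d = {k: round(v, decimals) for k, v in d.items()}
        return d


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """2x2 table with ACP = 1 as the positive class."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for arr, which in ((yt, "true"), (yp, "predicted")):
        bad = set(arr.tolist()) - {0, 1}
        if bad:
            raise ValueError(f"non-binary {which} labels: {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(counts: ConfusionCounts, auc: Optional[float] = None) -> EvaluationReport:
    """Accuracy, sensitivity, specificity, precision (percent) and MCC.

    Fractions with a zero denominator are reported as 0; in particular an
    MCC whose denominator vanishes (any zero marginal) is defined as 0, the
    no-correlation value.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion table")

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
    return EvaluationReport(
        accuracy=pct(tp + tn, total),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        precision=pct(tp, tp + fp),
        mcc=mcc,
        counts=counts,
        auc=auc,
    )


def evaluate_predictions(y_true, y_pred, scores=None) -> EvaluationReport:
    """Metrics from raw label vectors, with AUC when scores are supplied."""
    auc = None
    if scores is not None:
        _, _, _, auc = roc_and_auc(y_true, scores)
    return compute_metrics(confusion_counts(y_true, y_pred), auc=auc)


def roc_and_auc(y_true, scores):
    """ROC by threshold sweep over the distinct scores + trapezoid AUC.

    Returns ``(fpr, tpr, thresholds, auc)``.  Scores are positive-class
    probabilities in [0, 1].
    """
    yt = np.asarray(y_true, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if np.any((sc < 0) | (sc > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(yt)) < 2:
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, thresholds = _sk_roc_curve(yt, sc, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


@dataclass(frozen=True)
class FoldSplit:
    """A stratified partition into ``n_folds`` folds."""

    n_folds: int
    assignments: np.ndarray  # fold index per record
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def stratified_kfold(dataset_or_labels, n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded stratified folds: shuffle within class, assign round-robin.

    Per-fold class counts differ by at most 1 from perfect stratification.
    """
    if isinstance(dataset_or_labels, Dataset):
        y = dataset_or_labels.labels
    else:
        y = np.asarray(dataset_or_labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.full(len(y), -1, dtype=int)
    next_fold = 0  # carried across classes so total fold sizes stay balanced
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has {len(idx)} members, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        assignments[idx] = (next_fold + np.arange(len(idx))) % n_folds
        next_fold = (next_fold + len(idx)) % n_folds
    return FoldSplit(n_folds=n_folds, assignments=assignments, seed=seed)


@dataclass
class CVResult:
    """Per-fold reports plus mean/STD aggregation and pooled ROC scores."""

    fold_reports: list[EvaluationReport]
    split: FoldSplit
    pooled_true: np.ndarray
    pooled_scores: np.ndarray
    fold_predictions: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )  # (y_true, y_pred, scores) per fold

    @property
    def mean(self) -> dict[str, float]:
        return {
            name: float(np.mean([getattr(r, name) for r in self.fold_reports]))
            for name in METRIC_NAMES
        }

    @property
    def std(self) -> dict[str, float]:
        return {
            name: float(np.std([getattr(r, name) for r in self.fold_reports]))
            for name in METRIC_NAMES
        }

    def pooled_roc(self):
        return roc_and_auc(self.pooled_true, self.pooled_scores)

    @property
    def pooled_auc(self) -> float:
        return self.pooled_roc()[3]

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        """Per-fold metric table with a trailing mean (STD) row."""
        rows = [
            {"fold": i, **r.as_dict(decimals=None)}
            for i, r in enumerate(self.fold_reports)
        ]
        frame = pd.DataFrame(rows).set_index("fold")
        mean, std = self.mean, self.std
        frame.loc["mean"] = {k: mean.get(k, np.nan) for k in frame.columns}
        frame.loc["std"] = {k: std.get(k, np.nan) for k in frame.columns}
        return frame.round(decimals + 2)


def _fit_and_score(
    config: ModelConfig,
    stacks: Mapping[str, np.ndarray],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
) -> tuple[EvaluationReport, np.ndarray, np.ndarray]:
    cfg = ModelConfig.from_dict({**config.to_dict(), "seed": seed})
    model = build_mhcnn(cfg)
    tr = {rep: x[train_idx] for rep, x in stacks.items()}
    te = {rep: x[test_idx] for rep, x in stacks.items()}
    model.fit(tr, y[train_idx])
    probs = model.predict_proba(te)
    scores = probs[:, 1]
    preds = predict_label(probs)
    report = evaluate_predictions(y[test_idx], preds, scores)
    return report, preds, scores


def cross_validate(
    dataset: Dataset,
    config: ModelConfig,
    combination="C7",
    n_folds: int = 5,
    seed: int = 0,
    encoder: Optional[DatasetEncoder] = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the multi-headed classifier.

    Each fold trains a fresh model (seeded as ``seed + fold``) on the
    in-fold records and scores the untouched out-of-fold records.  The
    single per-dataset ROC curve is built from the pooled out-of-fold
    scores; per-fold AUCs are also reported.
    """
    combo = resolve_combination(combination)
    cfg = ModelConfig.from_dict({**config.to_dict(), "combination": list(combo)})
    encoder = encoder or DatasetEncoder()
    stacks, y = encoder.encode_dataset(dataset, combo, cfg.k)
    split = stratified_kfold(y, n_folds=n_folds, seed=seed)
    reports: list[EvaluationReport] = []
    fold_preds = []
    pooled_true = np.empty(len(y), dtype=int)
    pooled_scores = np.empty(len(y), dtype=float)
    for fold in range(n_folds):
        train_idx, test_idx = split.fold_indices(fold)
        report, preds, scores = _fit_and_score(
            cfg, stacks, y, train_idx, test_idx, seed=seed + fold
        )
        reports.append(report)
        fold_preds.append((y[test_idx], preds, scores))
        pooled_true[test_idx] = y[test_idx]
        pooled_scores[test_idx] = scores
    return CVResult(
        fold_reports=reports,
        split=split,
        pooled_true=pooled_true,
        pooled_scores=pooled_scores,
        fold_predictions=fold_preds,
    )


def independent_test(
    train_dataset: Dataset,
    test_dataset: Dataset,
    config: ModelConfig,
    combination="C7",
    encoder: Optional[DatasetEncoder] = None,
) -> tuple[EvaluationReport, MHCNN]:
    """Train once on ``train_dataset``, evaluate exactly once on ``test_dataset``.

    Early stopping uses an internal stratified validation split of the
    training data; the test set is never touched during fitting.  Shared
    record ids between the two datasets trigger a leakage warning.
    """
    shared = {r.id for r in train_dataset} & {r.id for r in test_dataset}
    if shared:
        warnings.warn(
            f"{len(shared)} record id(s) shared between train and test sets "
            f"(possible leakage), e.g. {sorted(shared)[:3]}"
        )
    combo = resolve_combination(combination)
    cfg = ModelConfig.from_dict({**config.to_dict(), "combination": list(combo)})
    encoder = encoder or DatasetEncoder()
    tr_stacks, y_tr = encoder.encode_dataset(train_dataset, combo, cfg.k)
    te_stacks, y_te = encoder.encode_dataset(test_dataset, combo, cfg.k)
    model = build_mhcnn(cfg)
    model.fit(tr_stacks, y_tr)
    probs = model.predict_proba(te_stacks)
    report = evaluate_predictions(y_te, predict_label(probs), probs[:, 1])
    return report, model


def combination_sweep(
    dataset: Dataset,
    config: ModelConfig,
    test_dataset: Optional[Dataset] = None,
    n_folds: int = 5,
    seed: int = 0,
    encoder: Optional[DatasetEncoder] = None,
    combinations: Sequence[str] = tuple(COMBINATIONS),
) -> pd.DataFrame:
    """Evaluate every representation combination C1..C7.

    In CV mode (no ``test_dataset``) each row carries the fold mean and STD
    of each metric; in independent mode each row is the single test-set
    report.  Returns a DataFrame indexed by combination name.
    """
    encoder = encoder or DatasetEncoder()
    rows = []
    for name in combinations:
        combo = COMBINATIONS[name]
        if test_dataset is None:
            res = cross_validate(
                dataset, config, combo, n_folds=n_folds, seed=seed, encoder=encoder
            )
            row = {"combination": name, "n_groups": len(combo)}
            for metric in METRIC_NAMES:
                row[metric] = res.mean[metric]
                row[f"{metric}_std"] = res.std[metric]
            row["auc"] = res.pooled_auc
        else:
            report, _ = independent_test(
                dataset, test_dataset, config, combo, encoder=encoder
            )
            row = {"combination": name, "n_groups": len(combo), **report.as_dict()}
        rows.append(row)
    return pd.DataFrame(rows).set_index("combination")


def export_roc(fpr: np.ndarray, tpr: np.ndarray, path: str | Path) -> None:
    """Write ROC points as a two-column delimited file (fpr, tpr)."""
    np.savetxt(path, np.column_stack([fpr, tpr]), fmt="%.6f", delimiter="\t",
               header="fpr\ttpr")


def plot_roc(fpr, tpr, auc: float, path: str | Path, title: str = "ROC") -> None:
    """Optional ROC plot (matplotlib imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
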