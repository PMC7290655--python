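"""Confusion-matrix metrics, ROC/AUC, and the cross-validation schemes.

Model quality is summarized by accuracy, sensitivity, specificity, PPV, NPV
and the Matthews correlation coefficient, plus the ROC curve (Sn vs 1-Sp)
and its AUC.  Nodes with at least 30 positive sites are evaluated by 4-, 6-,
8- or 10-fold stratified cross-validation; smaller clusters fall back to
leave-one-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

FOLD_CHOICES = (4, 6, 8, 10)
#: Below this many positives a node is validated by leave-one-out.
MIN_POSITIVES_FOR_KFOLD = 30


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("all counts are zero")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Ac, Sn, Sp, PPV, NPV and MCC from a confusion table.

    A metric whose denominator is zero is reported as ``None`` rather than
    silently coerced to 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def ratio(num, den):
        return num / den if den else None

    mcc_den = math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    return {
        "ac": ratio(tp + tn, tp + fp + tn + fn),
        "sn": ratio(tp, tp + fn),
        "sp": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "mcc": (tp * tn - fn * fp) / mcc_den if mcc_den else None,
    }


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC and the ROC polyline as (1-Sp, Sn) points.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(roc_auc_score(labels, scores)), np.column_stack([fpr, tpr])


@dataclass
class EvaluationReport:
    scheme: str
    auc: float
    roc_points: np.ndarray
    metrics: dict[str, float | None]
    n_positives: int
    n_negatives: int
    seed: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "auc": self.auc, "seed": self.seed,
                "n_positives": self.n_positives, "n_negatives": self.n_negatives,
                **self.metrics}

    def roc_to_tsv(self, path) -> None:
        np.savetxt(path, self.roc_points, delimiter="\t", header="fpr\ttpr", comments="")


def select_scheme(n_positives: int, k: int | str = "auto") -> str:
    """Pick the validation scheme for a node of the given positive count."""
    if k == "loo":
        return "loo"
    if k == "auto":
        return "10-fold" if n_positives >= MIN_POSITIVES_FOR_KFOLD else "loo"
    if k not in FOLD_CHOICES:
        raise ValueError(f"k must be one of {FOLD_CHOICES}, 'loo' or 'auto'")
    if k > n_positives:
        raise ValueError(f"cannot run {k}-fold validation with {n_positives} positives")
    return f"{k}-fold"


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1 per item), stratified by label."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = f
    return assignment


def cross_validate(benchmark, trainer, k: int | str = "auto", seed: int = 0,
                   threshold: float = 0.5) -> EvaluationReport:
    """Cross-validate a training procedure on one benchmark.

    ``trainer`` is a callable mapping a training :class:`BenchmarkDataset`
    to a scorer, itself a callable mapping a list of peptide windows to an
    array of scores in [0, 1].  The full procedure is refit inside every
    training fold and the held-out scores are pooled into a single ROC.
    """
    from .data_model import BenchmarkDataset

    items = benchmark.items
    labels = benchmark.labels
    scheme = select_scheme(len(benchmark.positives), k)

    scores = np.empty(len(items))
    if scheme == "loo":
        for i, item in enumerate(items):
            pos = [p for j, p in enumerate(benchmark.positives) if j != i]
            neg = [p for j, p in enumerate(benchmark.negatives)
                   if j != i - len(benchmark.positives)]
            if not pos or not neg:
                raise ValueError("leave-one-out needs at least 2 items per class")
            train = BenchmarkDataset(benchmark.node, pos, neg)
            scores[i] = trainer(train)([item])[0]
    else:
        nfolds = int(scheme.split("-")[0])
        folds = stratified_folds(labels, nfolds, seed)
        for f in range(nfolds):
            train = BenchmarkDataset(
                benchmark.node,
                [p for p, a in zip(benchmark.positives, folds) if a != f],
                [p for p, a in zip(benchmark.negatives, folds[len(benchmark.positives):])
                 if a != f])
            test_idx = np.flatnonzero(folds == f)
            scorer = trainer(train)
            scores[test_idx] = scorer([items[i] for i in test_idx])

    auc, points = roc_auc(scores, labels)
    pred = scores >= threshold
    counts = ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))), fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))), fn=int(np.sum(~pred & (labels == 1))))
    return EvaluationReport(scheme, auc, points, confusion_metrics(counts),
                            len(benchmark.positives), len(benchmark.negatives),
                            seed, scores=scores, labels=labels)
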