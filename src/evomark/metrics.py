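"""Balanced accuracy, AUROC, and repeated train/test evaluation.

AUROC is computed from pairwise concordance (ties credited 0.5), which is the
Mann-Whitney U statistic divided by ``n_pos * n_neg`` and agrees exactly with
trapezoidal ROC integration under the same tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .ensemble import FittedPipeline, fit_pipeline, model_complexity, pipeline_predict
from .weighting import LabeledMatrix

__all__ = [
    "MetricsError",
    "EvaluationReport",
    "confusion_counts",
    "balanced_accuracy",
    "auroc",
    "cross_validate",
    "paired_fold_ttest",
]


class MetricsError(ValueError):
    pass


@dataclass
class EvaluationReport:
    TP: int
    FP: int
    TN: int
    FN: int
    TPR: float
    TNR: float
    BAC: float
    AUROC: float
    n_pos: int
    n_neg: int
    fold_bac: list = field(default_factory=list)
    fold_auroc: list = field(default_factory=list)
    fold_complexity: list = field(default_factory=list)

    @property
    def bac_se(self) -> float:
        return _se(self.fold_bac)

    @property
    def auroc_se(self) -> float:
        return _se(self.fold_auroc)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("TP", "FP", "TN", "FN", "TPR", "TNR", "BAC", "AUROC",
              "n_pos", "n_neg")}
        if self.fold_bac:
            d["fold_bac"] = list(self.fold_bac)
            d["fold_auroc"] = list(self.fold_auroc)
            d["fold_complexity"] = list(self.fold_complexity)
            d["bac_se"] = self.bac_se
            d["auroc_se"] = self.auroc_se
        return d


def _se(values) -> float:
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(len(v)))


def _check_two_class(y: np.ndarray) -> None:
    if len(set(np.unique(y).tolist())) < 2:
        raise MetricsError("ground truth contains a single class")


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def balanced_accuracy(y_true, y_pred) -> float:
    """(TPR + TNR) / 2."""
    y_true = np.asarray(y_true)
    _check_two_class(y_true)
    tp, fp, tn, fn = confusion_counts(y_true, y_pred)
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return 0.5 * (tpr + tnr)


def auroc(scores, y_true) -> float:
    """Rank-based AUROC with 0.5 credit for tied scores."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    _check_two_class(y_true)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    ranks = stats.rankdata(scores)  # average ranks implement the tie credit
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _stratified_split(y: pd.Series, test_fraction: float,
                      rng: np.random.Generator):
    test_ids: list = []
    for cls in (0, 1):
        ids = np.asarray(y.index[y == cls])
        n_test = int(round(test_fraction * len(ids)))
        n_test = min(max(n_test, 1), len(ids) - 2)
        if n_test < 1 or len(ids) - n_test < 2:
            raise MetricsError("cohort too small for the requested split")
        test_ids.extend(rng.choice(ids, size=n_test, replace=False))
    test = set(test_ids)
    train_ids = [i for i in y.index if i not in test]
    return train_ids, test_ids


def cross_validate(matrix: LabeledMatrix, meta, conservation: pd.DataFrame,
                   config: RunConfig, *, mode: str = "es",
                   n_repeats: int = 10, test_fraction: float = 0.2,
                   seed: int = 0) -> EvaluationReport:
    """Repeated stratified train/test evaluation of the full pipeline.

    Per repeat, a fresh random split reserves ``test_fraction`` of each class
    for testing; the z-transform, statistical weights, and ensemble are fit
    on the training side only.  Reports pooled confusion counts plus per-fold
    BAC/AUROC (mean +/- SE via the report accessors).
    """
    master = np.random.SeedSequence(seed)
    fold_bac, fold_auroc, fold_cx = [], [], []
    tp = fp = tn = fn = 0
    all_scores, all_truth = [], []
    for child in master.spawn(n_repeats):
        split_seq, fit_seq = child.spawn(2)
        rng = np.random.default_rng(split_seq)
        train_ids, test_ids = _stratified_split(matrix.y, test_fraction, rng)
        train = matrix.subset(train_ids)
        fit_seed = int(fit_seq.generate_state(1)[0])
        fitted = fit_pipeline(train, meta, conservation, config,
                              mode=mode, seed=fit_seed)
        pred = pipeline_predict(fitted, matrix.X.loc[test_ids])
        y_test = matrix.y.loc[test_ids].to_numpy()
        fold_bac.append(balanced_accuracy(y_test, pred.labels.to_numpy()))
        fold_auroc.append(auroc(pred.confidence.to_numpy(), y_test))
        fold_cx.append(model_complexity(fitted.model))
        a, b, c, d = confusion_counts(y_test, pred.labels.to_numpy())
        tp, fp, tn, fn = tp + a, fp + b, tn + c, fn + d
        all_scores.append(pred.confidence.to_numpy())
        all_truth.append(y_test)

    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return EvaluationReport(
        TP=tp, FP=fp, TN=tn, FN=fn, TPR=tpr, TNR=tnr,
        BAC=float(np.mean(fold_bac)), AUROC=float(np.mean(fold_auroc)),
        n_pos=tp + fn, n_neg=tn + fp,
        fold_bac=fold_bac, fold_auroc=fold_auroc, fold_complexity=fold_cx)


def paired_fold_ttest(fold_a, fold_b) -> tuple[float, float]:
    """Paired t-test over matched folds; returns (t, p)."""
    res = stats.ttest_rel(np.asarray(fold_a, float), np.asarray(fold_b, float))
    return float(res.statistic), float(res.pvalue)
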