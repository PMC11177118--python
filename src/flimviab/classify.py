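"""Viability classification and screen-level statistics.

Covers the assay's decision machinery: stratified 10-fold cross-validated
AUROC of per-cell mean NMS against the PI death label, the per-fold
optimal operating threshold (Youden's J on the training folds), the
tri-state NMS bands (necroptotic below -0.28, viable in [-0.28, 0.33],
apoptotic/necrotic above 0.33), binary confusion metrics with "dead" as
the positive class, per-fragment percent-dead summaries, and the
NMS-vs-PI fragment regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .config import ThresholdBands
from .simulate import APOPTOTIC_NECROTIC, NECROPTOTIC, VIABLE

__all__ = ["CvResult", "FragmentSummary", "cv_auroc", "tri_state",
           "confusion_metrics", "fragment_viability", "fragment_regression"]


@dataclass
class CvResult:
    """Per-fold AUROC and optimal-threshold summary."""

    fold_auc: np.ndarray
    fold_threshold: np.ndarray
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def std_auc(self) -> float:
        return float(self.fold_auc.std(ddof=0))

    @property
    def mean_threshold(self) -> float:
        return float(self.fold_threshold.mean())

    @property
    def std_threshold(self) -> float:
        return float(self.fold_threshold.std(ddof=0))


@dataclass
class FragmentSummary:
    """Percent-dead readouts for one fragment at one timepoint."""

    fragment_id: str
    n_cells: int
    pct_dead_pi: float
    pct_dead_nms: float
    timepoint: str = ""


def cv_auroc(scores: np.ndarray, truth: np.ndarray, k: int = 10,
             seed: int = 0) -> CvResult:
    """Stratified k-fold cross-validated AUROC and optimal threshold.

    Per fold the ROC/AUC is computed on the held-out cells while the
    operating threshold maximizing Youden's J (sensitivity + specificity
    - 1) is computed on the training cells; both are summarized as mean
    and standard deviation over folds.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, thresholds = [], []
    for train, test in splitter.split(scores.reshape(-1, 1), truth):
        if truth[test].all() or not truth[test].any():
            raise ValueError("a fold lost one class; too few cells for k folds")
        aucs.append(roc_auc_score(truth[test], scores[test]))
        fpr, tpr, thr = roc_curve(truth[train], scores[train])
        j = tpr - fpr
        thresholds.append(thr[int(np.argmax(j))])
    return CvResult(fold_auc=np.asarray(aucs),
                    fold_threshold=np.asarray(thresholds), seed=seed)


def tri_state(mean_nms, bands: ThresholdBands = ThresholdBands()):
    """Tri-state call from a cell's mean NMS.

    Below ``t_left``: necroptotic; within the closed interval
    [``t_left``, ``t_right``]: viable; above ``t_right``:
    apoptotic/necrotic.  Dead means not viable.
    """
    x = np.asarray(mean_nms, dtype=float)
    out = np.where(x < bands.t_left, NECROPTOTIC,
                   np.where(x > bands.t_right, APOPTOTIC_NECROTIC, VIABLE))
    return out.item() if np.ndim(mean_nms) == 0 else out


def confusion_metrics(pred_dead: Sequence[bool], truth_dead: Sequence[bool]) -> dict:
    """Accuracy, sensitivity, specificity (percent) with dead as positive."""
    pred = np.asarray(pred_dead).astype(bool)
    truth = np.asarray(truth_dead).astype(bool)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("need equal-length nonempty prediction/truth")
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    n = pred.size
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return {"accuracy": 100.0 * (tp + tn) / n, "sensitivity": sens,
            "specificity": spec,
            "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp}}


def fragment_viability(cell_table: pd.DataFrame,
                       bands: ThresholdBands = ThresholdBands(),
                       fragment_id: str = "", timepoint: str = ""
                       ) -> FragmentSummary:
    """Percent dead by NMS tri-state (union of both dead classes) and by PI."""
    n = len(cell_table)
    if n == 0:
        raise ValueError("fragment has no retained cells")
    calls = tri_state(cell_table["mean_nms"].to_numpy(), bands)
    pct_nms = 100.0 * float((np.asarray(calls) != VIABLE).sum()) / n
    pct_pi = 100.0 * float(cell_table["pi_dead"].to_numpy().sum()) / n
    return FragmentSummary(fragment_id=fragment_id or str(
        cell_table["fragment_id"].iloc[0]), n_cells=n,
        pct_dead_pi=pct_pi, pct_dead_nms=pct_nms, timepoint=timepoint)


def fragment_regression(summaries: Iterable[FragmentSummary]) -> dict:
    """OLS of percent-dead-by-NMS on percent-dead-by-PI across fragments."""
    summaries = list(summaries)
    if len(summaries) < 3:
        raise ValueError("need at least 3 fragments")
    x = np.array([s.pct_dead_pi for s in summaries])
    y = np.array([s.pct_dead_nms for s in summaries])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the PI percent-dead predictor")
    fit = stats.linregress(x, y)
    return {"slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.rvalue ** 2, "p_value": fit.pvalue,
            "n_fragments": len(summaries)}
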