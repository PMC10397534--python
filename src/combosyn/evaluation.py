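"""Cross-validation protocols, classification metrics and model comparison.

Protocols: shuffled k-fold over samples, leave-one-cell-line-out (every
sample of one cell line is held out per fold), and a cross-dataset mode
(train on one bundle, test on another).  Metrics follow the usual
classification battery at a fixed 0.5 operating point — accuracy,
recall, F1 — plus threshold-free AUC-ROC (rank statistic with tie
correction) and AUC-PR (step integration of the precision--recall
curve).  Models are compared with a paired two-sided t-test on per-fold
metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_recall_curve,
    recall_score,
    roc_auc_score,
)

from .datasets import SynergySample


@dataclass
class SplitPlan:
    mode: str                                   # kfold | leave_one_cell_line_out | cross_dataset
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    seed: int = 0
    fold_names: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


@dataclass
class MetricReport:
    acc: float
    recall: float
    f1: float
    auc_roc: float | None
    auc_pr: float | None

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
        }


def make_kfold(samples: list[SynergySample] | int, k: int = 5, seed: int = 0) -> SplitPlan:
    """Shuffled k-fold plan with near-equal test parts (sizes differ by <= 1)."""
    n = samples if isinstance(samples, int) else len(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts = np.array_split(order, k)
    folds = [
        (np.sort(np.concatenate([p for j, p in enumerate(parts) if j != i])),
         np.sort(parts[i]))
        for i in range(k)
    ]
    return SplitPlan(mode="kfold", folds=folds, seed=seed,
                     fold_names=[f"fold{i}" for i in range(k)])


def make_loco(samples: list[SynergySample]) -> SplitPlan:
    """Leave-one-cell-line-out plan: one fold per distinct cell id."""
    cells = sorted({s.cell_id for s in samples})
    if len(cells) < 2:
        raise ValueError("leave-one-cell-line-out needs at least 2 cell lines")
    cell_arr = np.array([s.cell_id for s in samples])
    folds = []
    for cell in cells:
        test = np.flatnonzero(cell_arr == cell)
        train = np.flatnonzero(cell_arr != cell)
        folds.append((train, test))
    return SplitPlan(mode="leave_one_cell_line_out", folds=folds,
                     fold_names=list(cells))


def auc_roc_brute_force(labels: np.ndarray, scores: np.ndarray) -> float:
    """All positive-negative pairs AUC with half credit for ties (oracle)."""
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined for a single-class set")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def auc_pr_step(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC-PR by right-step integration of the precision--recall curve."""
    precision, recall, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns recall decreasing; step-integrate
    return float(-np.sum(np.diff(recall) * precision[:-1]))


def evaluate_predictions(labels: np.ndarray, scores: np.ndarray,
                         threshold: float = 0.5) -> MetricReport:
    """Score predicted probabilities against binary labels.

    ACC/recall/F1 use the fixed threshold; the AUCs are reported as None
    (with a warning) when the test set contains a single class.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    preds = (scores > threshold).astype(int)
    acc = accuracy_score(labels, preds)
    rec = recall_score(labels, preds, zero_division=0)
    f1 = f1_score(labels, preds, zero_division=0)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class test set: AUC-ROC / AUC-PR undefined")
        return MetricReport(acc=acc, recall=rec, f1=f1, auc_roc=None, auc_pr=None)
    return MetricReport(
        acc=acc,
        recall=rec,
        f1=f1,
        auc_roc=float(roc_auc_score(labels, scores)),
        auc_pr=auc_pr_step(labels, scores),
    )


def compare_models(metrics_a: np.ndarray, metrics_b: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test on per-fold metrics of two models."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D metric vectors")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least 2 folds")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        warnings.warn("zero variance of paired differences: p-value degenerate")
        return (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class GridSpec:
    """Hyperparameter grids; defaults are the printed search spaces."""

    clusters: tuple = (200, 300, 400, 600)
    learning_rate: tuple = (0.0001, 0.001, 0.01, 0.1)
    lambda_grid: tuple = (0.25, 0.5, 1.0)
    patch_size: tuple = (20, 30, 40, 50, 60)
    overlap_ratio: tuple = (0.25, 1 / 3, 0.5, 0.75)

    def points(self, axes: list[str]) -> list[dict]:
        """Cartesian product over a subset of grid axes."""
        values = [getattr(self, ax) for ax in axes]
        return [dict(zip(axes, combo)) for combo in itertools.product(*values)]


def grid_search(fit_and_score, grid: GridSpec, axes: list[str]) -> tuple[dict, list[dict]]:
    """Exhaustive sweep over ``axes`` of the grid.

    ``fit_and_score(point) -> float`` must return the selection criterion
    (mean validation AUC-PR); returns the argmax point and the full
    results table (one row per point with its criterion).
    """
    table = []
    for point in grid.points(axes):
        score = fit_and_score(point)
        table.append({**point, "criterion": score})
    best = max(table, key=lambda row: row["criterion"])
    best_point = {k: v for k, v in best.items() if k != "criterion"}
    return best_point, table
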