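"""Benchmark metrics: precision-recall curves, average precision, truth ranks
and bootstrap confidence bands for injected-outlier experiments.

Cells are ranked matrix-wide by ascending P-value (ties broken by descending
|z-hat| when available, else by stable cell order); the area under the PR
curve is the average-precision step rule — the mean of the precision values
at the ranks where true outliers are hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import RealMatrix
from .injection import TruthMask

__all__ = ["PRCurve", "pr_curve", "truth_ranks", "bootstrap_pr"]


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def _ranking(pvalues: RealMatrix, zhat: RealMatrix | None) -> np.ndarray:
    """Indices of cells from most to least outlier-like."""
    p = pvalues.values.ravel()
    if zhat is not None:
        if zhat.values.shape != pvalues.values.shape:
            raise ValueError("z-hat shape does not match P-value shape")
        keys = (np.arange(p.size), -np.abs(zhat.values.ravel()), p)
    else:
        keys = (np.arange(p.size), p)
    return np.lexsort(keys)


def _check(pvalues: RealMatrix, truth: TruthMask) -> np.ndarray:
    t = truth.mask.ravel()
    if truth.mask.shape != pvalues.values.shape:
        raise ValueError("truth mask shape does not match P-value shape")
    if t.sum() == 0:
        raise ValueError("truth mask has no true cells")
    return t


def _pr_from_order(order: np.ndarray, truth_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hits = truth_flat[order]
    tp = np.cumsum(hits)
    precision = tp / np.arange(1, hits.size + 1)
    recall = tp / truth_flat.sum()
    return precision, recall


def pr_curve(
    pvalues: RealMatrix, truth: TruthMask, zhat: RealMatrix | None = None
) -> PRCurve:
    """Precision/recall at every rank plus average precision."""
    t = _check(pvalues, truth)
    order = _ranking(pvalues, zhat)
    precision, recall = _pr_from_order(order, t)
    hits = t[order]
    auc = float(precision[hits].sum() / t.sum())
    return PRCurve(
        thresholds=pvalues.values.ravel()[order],
        precision=precision,
        recall=recall,
        auc=auc,
    )


def truth_ranks(pvalues: RealMatrix, truth: TruthMask) -> list[int]:
    """1-based ranks of the true cells in the global ascending-P ordering.

    Ties share the minimum rank of the tied block.
    """
    t = _check(pvalues, truth)
    p = pvalues.values.ravel()
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # min rank of each tied block: first index where the value appears
    ranks = np.searchsorted(sorted_p, p, side="left") + 1
    return [int(r) for r in ranks[t]]


def _precision_at_recall_grid(
    precision: np.ndarray, recall: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Precision at the first rank achieving each grid recall (step rule)."""
    idx = np.searchsorted(recall, grid, side="left")
    idx = np.minimum(idx, recall.size - 1)
    return precision[idx]


def bootstrap_pr(
    pvalues: RealMatrix,
    truth: TruthMask,
    n_boot: int = 200,
    seed: int = 1,
    zhat: RealMatrix | None = None,
    recall_grid: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Percentile confidence bands for precision at a fixed recall grid.

    Truth cells and non-truth cells are resampled with replacement (each
    stratum at its own size) ``n_boot`` times; returns the 2.5/97.5 percentile
    precision plus the point estimate on the grid.
    """
    t = _check(pvalues, truth)
    if t.sum() < 2:
        raise ValueError("need at least 2 true cells for bootstrap bands")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if recall_grid is None:
        recall_grid = np.linspace(0.05, 1.0, 20)
    order = _ranking(pvalues, zhat)
    # rank of every cell (0 = most outlier-like)
    rank_of = np.empty(t.size, dtype=np.int64)
    rank_of[order] = np.arange(t.size)
    true_ranks = np.sort(rank_of[t])
    false_ranks = np.sort(rank_of[~t])

    def precision_on_grid(tr: np.ndarray, fr: np.ndarray) -> np.ndarray:
        tr = np.sort(tr)
        n_true = tr.size
        # at the rank of the k-th true cell: k true positives, plus however
        # many false cells rank at or before it
        fp = np.searchsorted(fr, tr, side="left")
        tp = np.arange(1, n_true + 1)
        prec = tp / (tp + fp)
        rec = tp / n_true
        return _precision_at_recall_grid(prec, rec, recall_grid)

    point = precision_on_grid(true_ranks, false_ranks)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, recall_grid.size))
    for b in range(n_boot):
        tr = rng.choice(true_ranks, size=true_ranks.size, replace=True)
        fr = np.sort(rng.choice(false_ranks, size=false_ranks.size, replace=True))
        boot[b] = precision_on_grid(tr, fr)
    lower = np.percentile(boot, 2.5, axis=0)
    upper = np.percentile(boot, 97.5, axis=0)
    return {
        "recall": recall_grid,
        "precision": point,
        "lower": lower,
        "upper": upper,
    }
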