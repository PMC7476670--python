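"""Slide-level aggregation, cross-validation folds, ensembling, ROC/AUC with
bootstrap confidence intervals, threshold metrics, and probability-map
rendering.

The slide posterior is the arithmetic mean of the posteriors of its tumor
patches; the ensemble posterior is the unweighted mean over the K
cross-validation models. AUC is the Mann-Whitney concordance probability
(ties counted 1/2); confidence intervals come from a stratified percentile
bootstrap (resampling positives and negatives separately, so every resample
contains both classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "slide_probability",
    "make_slide_folds",
    "ensemble_average",
    "roc_auc",
    "roc_points",
    "bootstrap_auc_ci",
    "threshold_metrics",
    "evaluate_scores",
    "render_probability_map",
]


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray([1 if lab in (1, "POS", True) else 0 for lab in labels])
    return y


def slide_probability(patch_posteriors) -> float:
    """Mean positive-class posterior over a slide's tumor patches.

    Accepts a sequence of patch posteriors or a ProbabilityMap-like object
    with ``probs`` and ``tumor_cells`` attributes (mean over tumor cells).
    """
    if hasattr(patch_posteriors, "probs") and hasattr(patch_posteriors, "tumor_cells"):
        cells = np.asarray(patch_posteriors.probs)[
            np.asarray(patch_posteriors.tumor_cells) != 0]
        if cells.size == 0:
            raise ValueError("probability map has no tumor cells")
        return float(cells.mean())
    arr = np.asarray(list(patch_posteriors), dtype=float)
    if arr.size == 0:
        raise ValueError("slide has no tumor patches")
    return float(arr.mean())


@dataclass
class FoldSplit:
    assignment: dict[str, int]   # slide_id -> fold in {1..k}
    k: int

    def fold_slides(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def val_slides(self, fold: int) -> list[str]:
        return self.fold_slides(fold)

    def train_slides(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f != fold]

    def rotations(self):
        """The K train/validation rotations (model k validates on fold k)."""
        return [(k, self.train_slides(k), self.val_slides(k))
                for k in range(1, self.k + 1)]


def make_slide_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified slide-level K-fold assignment.

    Greedy dealing of each class's shuffled slides into the currently
    least-loaded fold guarantees per-fold total sizes and per-fold
    positive counts each differ by at most one.
    """
    if len(manifest) < k:
        raise ValueError(f"need at least k={k} slides, got {len(manifest)}")
    y = _as_binary_labels(manifest["label"])
    if y.min() == y.max():
        raise ValueError("both classes must be present to stratify folds")
    rng = np.random.default_rng(seed)
    slide_ids = np.asarray(manifest["slide_id"], dtype=object)
    assignment: dict[str, int] = {}
    class_counts = {f: 0 for f in range(1, k + 1)}
    total_counts = {f: 0 for f in range(1, k + 1)}
    for cls in (1, 0):
        ids = slide_ids[y == cls]
        if len(ids) < k:
            warnings.warn(f"class {cls} has fewer than {k} slides; "
                          "stratification is best-effort")
        ids = ids[rng.permutation(len(ids))]
        for f in class_counts:
            class_counts[f] = 0
        for sid in ids:
            fold = min(class_counts,
                       key=lambda f: (class_counts[f], total_counts[f], f))
            assignment[str(sid)] = fold
            class_counts[fold] += 1
            total_counts[fold] += 1
    return FoldSplit(assignment=assignment, k=k)


def ensemble_average(per_model_posteriors) -> np.ndarray:
    """Element-wise unweighted mean of M aligned posterior lists."""
    lists = [np.asarray(p, dtype=float) for p in per_model_posteriors]
    n = {len(p) for p in lists}
    if len(n) != 1:
        raise ValueError(f"posterior lists have mismatched lengths: {sorted(n)}")
    return np.mean(lists, axis=0)


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney pairwise concordance probability (ties 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve as (threshold, sensitivity, specificity) rows, thresholds
    descending; passes through (sens=0) and (sens=1) endpoints."""
    y = _as_binary_labels(labels)
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thr, "sensitivity": tpr,
                         "specificity": 1.0 - fpr})


def _auc_rows(score_matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for a (B, n) score matrix vs fixed labels."""
    ranks = rankdata(score_matrix, axis=1)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    pos_sum = ranks[:, y == 1].sum(axis=1)
    return (pos_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, alpha: float = 0.05,
                     seed: int = 0) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    bpos = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    bneg = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    mat = np.concatenate([bpos, bneg], axis=1)
    yb = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    aucs = _auc_rows(mat, yb)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics; predict positive iff score > threshold
    (strict, so a score exactly at the threshold is called negative)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    pred = s > threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"accuracy": (tp + tn) / len(y), "sensitivity": sens,
            "specificity": spec, "precision": prec, "f1": f1,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


@dataclass
class MetricsReport:
    auc: float
    ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    n_pos: int
    n_neg: int

    def as_row(self, level: str = "", variant: str = "") -> dict:
        return {"level": level, "variant": variant, "auc": self.auc,
                "ci_low": self.ci[0], "ci_high": self.ci[1],
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1, "n_pos": self.n_pos, "n_neg": self.n_neg}


def evaluate_scores(scores, labels, n_boot: int = 2000, alpha: float = 0.05,
                    seed: int = 0, threshold: float = 0.5) -> MetricsReport:
    """AUC with bootstrap CI plus threshold-0.5 metrics in one report."""
    y = _as_binary_labels(labels)
    tm = threshold_metrics(scores, labels, threshold)
    return MetricsReport(
        auc=roc_auc(scores, labels),
        ci=bootstrap_auc_ci(scores, labels, n_boot=n_boot, alpha=alpha, seed=seed),
        accuracy=tm["accuracy"], sensitivity=tm["sensitivity"],
        specificity=tm["specificity"], precision=tm["precision"], f1=tm["f1"],
        n_pos=int(y.sum()), n_neg=int((1 - y).sum()))


_GREY = np.array([158, 158, 158], dtype=float)     # negative end
_BLUE = np.array([40, 80, 220], dtype=float)       # positive end
_BG = np.array([255, 255, 255], dtype=float)       # off-tumor background


def render_probability_map(pmap, out_path=None, cell_px: int = 16) -> np.ndarray:
    """Render a probability map: grey (negative) to blue (positive) over
    tumor cells, white background off-mask; returns the RGB array and
    optionally writes a PNG."""
    probs = np.asarray(pmap.probs, dtype=float)
    mask = np.asarray(pmap.tumor_cells) != 0
    rgb = np.empty(probs.shape + (3,), dtype=float)
    rgb[...] = _BG
    lerp = _GREY[None, :] + probs[mask][:, None] * (_BLUE - _GREY)[None, :]
    rgb[mask] = lerp
    img = np.kron(rgb, np.ones((cell_px, cell_px, 1)))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(img).save(out_path)
    return img
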