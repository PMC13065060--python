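"""Per-slice per-class evaluation metrics with absent-class semantics.

For every (slice, class) pair we form one-vs-rest voxel confusion counts
and derive Dice, Sensitivity, Specificity, Precision and IoU.  When a
slice has no ground-truth positives for a class, Dice and Sensitivity are
recorded as missing (NaN) and omitted from means; Precision and IoU are
missing when no positives are predicted either (TP=0, FP=0) and collapse
to 0 when false positives exist (TP=0, FP>0).  Macro scores are the
unweighted mean over foreground classes that occur anywhere in the test
ground truth; background (class 0) is always excluded from macros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "confusion_counts", "per_class_metrics", "metric_table", "macro_average",
    "slice_error_series", "aggregate_seeds", "hard_macro_dice",
]

N_CLASSES = 13
METRIC_NAMES = ("dice", "sensitivity", "specificity", "precision", "iou")


def confusion_counts(pred_labels: np.ndarray, gt_labels: np.ndarray,
                     n_classes: int = N_CLASSES) -> np.ndarray:
    """One-vs-rest (TP, FP, FN, TN) per class for one slice.

    Returns an (n_classes, 4) integer array; each row sums to H*W.
    """
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("prediction and ground truth shapes differ")
    pred = pred_labels.ravel()
    gt = gt_labels.ravel()
    total = pred.size
    joint = np.bincount(gt * n_classes + pred,
                        minlength=n_classes * n_classes
                        ).reshape(n_classes, n_classes)
    tp = np.diag(joint)
    fn = joint.sum(axis=1) - tp   # gt == c, pred != c
    fp = joint.sum(axis=0) - tp   # pred == c, gt != c
    tn = total - tp - fn - fp
    return np.stack([tp, fp, fn, tn], axis=1)


def per_class_metrics(counts: np.ndarray, gt_present: bool) -> dict:
    """Eq-style metrics from one class's (TP, FP, FN, TN) counts."""
    tp, fp, fn, tn = (int(v) for v in counts)
    out: dict[str, float] = {}
    out["dice"] = 2 * tp / (2 * tp + fp + fn) if gt_present else np.nan
    out["sensitivity"] = tp / (tp + fn) if gt_present else np.nan
    out["specificity"] = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    if tp == 0 and fp == 0:
        out["precision"] = np.nan
        out["iou"] = np.nan
    elif tp == 0:
        out["precision"] = 0.0
        out["iou"] = 0.0
    else:
        out["precision"] = tp / (tp + fp)
        out["iou"] = tp / (tp + fp + fn)
    return out


def metric_table(pred_volume: np.ndarray, gt_volume: np.ndarray,
                 n_classes: int = N_CLASSES) -> pd.DataFrame:
    """Tidy per-(slice, class) table of counts and metrics for a volume.

    ``pred_volume`` and ``gt_volume`` are (Z, H, W) integer label maps.
    """
    rows = []
    for z in range(pred_volume.shape[0]):
        counts = confusion_counts(pred_volume[z], gt_volume[z], n_classes)
        present = np.bincount(gt_volume[z].ravel(), minlength=n_classes) > 0
        for c in range(n_classes):
            rec = {"slice": z, "class_id": c,
                   "tp": int(counts[c, 0]), "fp": int(counts[c, 1]),
                   "fn": int(counts[c, 2]), "tn": int(counts[c, 3]),
                   "gt_present": bool(present[c])}
            rec.update(per_class_metrics(counts[c], bool(present[c])))
            rows.append(rec)
    return pd.DataFrame(rows)


def macro_average(table: pd.DataFrame) -> dict:
    """Per-class slice means (NaN-omitting) and foreground macro means.

    Classes absent from the entire test ground truth are excluded from the
    macro; background (class 0) is always excluded.
    """
    per_class = {}
    macro = {}
    fg = table[table["class_id"] > 0]
    present_classes = sorted(
        fg.loc[fg["gt_present"], "class_id"].unique().tolist())
    for metric in METRIC_NAMES:
        means = fg.groupby("class_id")[metric].mean()  # pandas skips NaN
        per_class[metric] = means.to_dict()
        vals = [means[c] for c in present_classes
                if c in means and np.isfinite(means[c])]
        macro[metric] = float(np.mean(vals)) if vals else np.nan
    return {"per_class": per_class, "macro": macro,
            "present_classes": present_classes}


def hard_macro_dice(pred_volume: np.ndarray, gt_volume: np.ndarray,
                    n_classes: int = N_CLASSES) -> float:
    """Macro Dice of hard labels (the training monitor quantity)."""
    return macro_average(metric_table(pred_volume, gt_volume, n_classes)
                         )["macro"]["dice"]


def slice_error_series(per_slice_dice: pd.DataFrame, groups: dict,
                       ) -> dict:
    """Per-slice Dice error e = 1 - mean Dice over each class group.

    ``per_slice_dice`` is a tidy table with columns (slice, class_id, dice,
    gt_present); ``groups`` maps a name to a set of class ids.  Returns per
    group the error series plus its mean and half-width 1.96 * sample SD.
    """
    out = {}
    for name, class_ids in groups.items():
        if not class_ids:
            raise ValueError(f"empty class group {name!r}")
        sub = per_slice_dice[per_slice_dice["class_id"].isin(set(class_ids))]
        series = 1.0 - sub.groupby("slice")["dice"].mean()
        e = series.to_numpy(dtype=float)
        sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
        out[name] = {"slices": series.index.to_numpy(),
                     "errors": e,
                     "mean": float(np.nanmean(e)) if e.size else np.nan,
                     "half_width": 1.96 * sd}
    return out


def aggregate_seeds(per_seed_values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation over seed repeats."""
    vals = np.asarray(list(per_seed_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 seed values to aggregate")
    return float(vals.mean()), float(vals.std(ddof=1))
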