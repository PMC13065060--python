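"""Training protocol, scan-level splits, and external-test evaluation.

The protocol mirrors a unified spectral-CT segmentation setup: Adam
(learning rate 1e-4, no weight decay), ReduceLROnPlateau (factor 0.5,
patience 5) and early stopping (patience 12, minimum improvement 1e-3),
both monitored on validation macro Dice (maximize), capped at 200 epochs.
Splitting is at the scan level: one scan is held out for external testing
and the development scans are divided into train/validation, so no slice
of a validation or test scan is ever seen in training.

Desk-scale conveniences (small crops with foreground-biased sampling,
validation-slice subsetting) are protocol fields with conservative
defaults; they change problem size, never the optimization rules.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentParams, augment_sample
from .dataio import load_manifest, load_scan
from .losses import composite_loss
from .materials import CLASS_NAMES, HA_GROUP, IODINE_GROUP
from .metrics import (aggregate_seeds, hard_macro_dice, macro_average,
                      metric_table, slice_error_series)
from .model import (NetworkConfig, build_network, load_checkpoint,
                    predict_labels, save_checkpoint)
from .nn import Adam

__all__ = [
    "SplitPlan", "TrainProtocol", "RunHistory", "ReduceLROnPlateau",
    "EarlyStopping", "make_split", "train_model", "evaluate_external",
    "run_ablation", "load_dataset", "predict_volume", "LeakageError",
]


class LeakageError(RuntimeError):
    """Raised when evaluation is attempted on a scan seen in training."""


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint scan-id partitions (leakage guard)."""

    train_scans: tuple
    val_scans: tuple
    test_scans: tuple

    def __post_init__(self) -> None:
        parts = [set(self.train_scans), set(self.val_scans), set(self.test_scans)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("scan partitions overlap")


@dataclass(frozen=True)
class TrainProtocol:
    """Optimizer, scheduler, early stopping and epoch/batch structure."""

    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    early_stop_patience: int = 12
    min_delta: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 4
    crop_size: int | None = None
    fg_crop_prob: float = 0.9
    val_max_slices: int | None = None
    augment: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self) -> None:
        if self.min_delta <= 0:
            raise ValueError("min_delta must be positive")


@dataclass
class RunHistory:
    """Per-epoch record of one training run."""

    train_loss: list = field(default_factory=list)
    val_macro_dice: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    wall_time_s: list = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


class ReduceLROnPlateau:
    """Halve the learning rate after ``patience`` epochs without improvement.

    Monitor mode is maximize; an epoch improves when the monitored value
    exceeds the best seen by at least ``min_delta``.  The reduction fires on
    the (patience+1)-th consecutive non-improving epoch.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 5, min_delta: float = 1e-3):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> bool:
        """Feed one epoch's monitor value; returns True if LR was reduced."""
        if value >= self.best + self.min_delta:
            self.best = value
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr *= self.factor
            self.bad_epochs = 0
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without minimum improvement."""

    def __init__(self, patience: int = 12, min_delta: float = 1e-3):
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.best_epoch = -1
        self.bad_epochs = 0

    def step(self, value: float, epoch: int) -> bool:
        """Feed one epoch's monitor value; returns True when training should stop."""
        if value >= self.best + self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def make_split(scan_ids, seed: int = 0) -> SplitPlan:
    """Scan-level split: 1 external test scan, remaining scans ~80/20 train/val.

    With 5 scans this yields (3 train, 1 val, 1 test): the exact 80/20
    ratio is secondary to the scan-level anti-leakage granularity.
    """
    ids = list(scan_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 scans to split")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test = [order.pop()]
    n_dev = len(order)
    n_val = max(1, round(0.2 * n_dev))
    val = order[:n_val]
    train = order[n_val:]
    return SplitPlan(tuple(sorted(train)), tuple(sorted(val)), tuple(sorted(test)))


# ---------------------------------------------------------------------------
# data handling

def standardize_scan(values: np.ndarray, blind: bool = False) -> np.ndarray:
    """Per-scan per-bin zero-mean/unit-variance standardization.

    For the energy-blind control the RAW bins are averaged first and the
    single collapsed channel is standardized afterwards; standardizing
    per-bin first would reweight bins by 1/sigma_f and leak spectral shape
    into a model that is meant to see only band-integrated intensity.
    """
    v = values.astype(np.float32)
    if blind:
        v = v.mean(axis=1, keepdims=True)
    mean = v.mean(axis=(0, 2, 3), keepdims=True)
    std = v.std(axis=(0, 2, 3), keepdims=True)
    return (v - mean) / np.maximum(std, 1e-8)


def load_dataset(data_dir, blind: bool = False) -> dict:
    """Load every scan in a simulated-dataset directory, standardized."""
    data_dir = Path(data_dir)
    manifest = load_manifest(data_dir)
    scans = {}
    for rec in manifest["scans"]:
        vol, lab, scan_id = load_scan(data_dir / rec["file"])
        scans[scan_id] = {
            "values": standardize_scan(vol.values, blind=blind),
            "labels": lab.labels.astype(np.int64),
            "voxel_size_mm": vol.voxel_size_mm,
        }
    return scans


def _sample_crop(img: np.ndarray, lab: np.ndarray, size: int,
                 fg_prob: float, rng: np.random.Generator):
    """Random crop, biased to center on a foreground voxel with prob fg_prob."""
    F_, H, W = img.shape
    if size >= H:
        return img, lab
    fg = np.argwhere(lab > 0)
    if fg.size and rng.random() < fg_prob:
        cy, cx = fg[rng.integers(len(fg))]
        cy += rng.integers(-size // 2, size // 2 + 1)
        cx += rng.integers(-size // 2, size // 2 + 1)
        top = int(np.clip(cy - size // 2, 0, H - size))
        left = int(np.clip(cx - size // 2, 0, W - size))
    else:
        top = int(rng.integers(0, H - size + 1))
        left = int(rng.integers(0, W - size + 1))
    return (img[:, top:top + size, left:left + size],
            lab[top:top + size, left:left + size])


def _val_slice_indices(n_slices: int, max_slices: int | None) -> np.ndarray:
    if max_slices is None or n_slices <= max_slices:
        return np.arange(n_slices)
    return np.linspace(0, n_slices - 1, max_slices).round().astype(int)


def _predict_slice_tiled(net, img: np.ndarray, tile: int) -> np.ndarray:
    """Patch-based inference: predict non-overlapping tiles at the training
    patch size (so instance-norm statistics match training) and stitch."""
    F_, H, W = img.shape
    xs, pos = [], []
    for top in range(0, H, tile):
        for left in range(0, W, tile):
            xs.append(img[:, top:top + tile, left:left + tile][None])
            pos.append((top, left))
    preds = predict_labels(net.forward(np.stack(xs)))
    out = np.zeros((H, W), dtype=np.int64)
    for (top, left), p in zip(pos, preds):
        out[top:top + tile, left:left + tile] = p
    return out


def predict_volume(net, values: np.ndarray, slice_indices=None,
                   tile: int | None = None) -> np.ndarray:
    """Argmax label maps for (a subset of) the slices of a standardized scan.

    When ``tile`` is given (networks trained on crops of that size),
    slices are predicted as stitched non-overlapping tiles.
    """
    Z = values.shape[0]
    idx = np.arange(Z) if slice_indices is None else np.asarray(slice_indices)
    out = []
    for z in idx:
        if tile and tile < values.shape[-1]:
            out.append(_predict_slice_tiled(net, values[z], tile))
        else:
            logits = net.forward(values[z][None, None])
            out.append(predict_labels(logits)[0])
    return np.stack(out)


def _validation_macro_dice(net, scans: dict, val_ids, max_slices,
                           tile: int | None = None) -> float:
    preds, gts = [], []
    for sid in val_ids:
        sc = scans[sid]
        idx = _val_slice_indices(sc["labels"].shape[0], max_slices)
        preds.append(predict_volume(net, sc["values"], idx, tile=tile))
        gts.append(sc["labels"][idx])
    dice = hard_macro_dice(np.concatenate(preds), np.concatenate(gts))
    return float(dice) if np.isfinite(dice) else 0.0


# ---------------------------------------------------------------------------
# training

def train_model(config: NetworkConfig, protocol: TrainProtocol,
                split: SplitPlan, data_dir, seed: int,
                out_dir=None, verbose: bool = False,
                ) -> tuple[Path | None, RunHistory, "object"]:
    """Train one network under the protocol; returns (checkpoint, history, net).

    All randomness (init, batch order, crops, augmentation) derives from
    ``seed``.  The checkpoint restored and saved is the one with maximal
    validation macro Dice.  A checkpoint file is written only when
    ``out_dir`` is given.
    """
    if not split.train_scans:
        raise ValueError("empty training partition")
    blind = config.variant == "blind_control"
    scans = load_dataset(data_dir, blind=blind)
    for sid in (*split.train_scans, *split.val_scans, *split.test_scans):
        if sid not in scans:
            raise FileNotFoundError(f"scan {sid!r} missing from {data_dir}")

    net = build_network(config, seed=seed)
    opt = Adam(net.params(), lr=protocol.learning_rate,
               weight_decay=protocol.weight_decay)
    sched = ReduceLROnPlateau(opt, protocol.scheduler_factor,
                              protocol.scheduler_patience, protocol.min_delta)
    stopper = EarlyStopping(protocol.early_stop_patience, protocol.min_delta)
    rng = np.random.default_rng([seed, 0xA06])
    history = RunHistory()

    train_slices = [(sid, z) for sid in split.train_scans
                    for z in range(scans[sid]["labels"].shape[0])]
    best_params = None
    best_val = -np.inf
    best_epoch = -1
    stop_reason = "max_epochs"
    for epoch in range(protocol.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_slices))
        losses = []
        for start in range(0, len(order), protocol.batch_size):
            xs, ys = [], []
            for j in order[start:start + protocol.batch_size]:
                sid, z = train_slices[j]
                img = scans[sid]["values"][z]
                lab = scans[sid]["labels"][z]
                if protocol.crop_size:
                    img, lab = _sample_crop(img, lab, protocol.crop_size,
                                            protocol.fg_crop_prob, rng)
                img, lab = augment_sample(img, lab, protocol.augment, rng)
                xs.append(img[None])     # add channel axis
                ys.append(lab)
            x = np.stack(xs).astype(np.float32)
            y = np.stack(ys)
            logits = net.forward(x)
            loss, dlogits = composite_loss(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch} "
                    f"(lr={opt.lr:g}); aborting run")
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_dice = _validation_macro_dice(net, scans, split.val_scans,
                                          protocol.val_max_slices,
                                          tile=protocol.crop_size)
        history.train_loss.append(float(np.mean(losses)))
        history.val_macro_dice.append(val_dice)
        history.learning_rate.append(float(opt.lr))
        history.wall_time_s.append(time.perf_counter() - t0)
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  "
                  f"val macro Dice {val_dice:.4f}  lr {opt.lr:g}")
        if val_dice > best_val or best_params is None:
            best_val = val_dice
            best_epoch = epoch
            best_params = [p.data.copy() for p in net.params()]
        stop = stopper.step(val_dice, epoch)
        sched.step(val_dice)
        if stop:
            stop_reason = "early_stopping"
            break
    history.best_epoch = int(best_epoch)
    history.stop_reason = stop_reason

    for p, w in zip(net.params(), best_params):
        p.data = w
    ckpt_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = out_dir / f"{config.variant}_seed{seed}.npz"
        save_checkpoint(ckpt_path, net, seed,
                        extra={"split": asdict(split),
                               "infer_tile": protocol.crop_size,
                               "history": history.to_dict()})
        with open(out_dir / f"{config.variant}_seed{seed}_history.json",
                  "w") as fh:
            json.dump(history.to_dict(), fh, indent=2)
    return ckpt_path, history, net


# ---------------------------------------------------------------------------
# evaluation

def class_groups() -> dict:
    """HA and iodine class-id groups for the slice-error analysis."""
    name_to_id = {v: k for k, v in CLASS_NAMES.items()}
    return {"HA": {name_to_id[n] for n in HA_GROUP},
            "iodine": {name_to_id[n] for n in IODINE_GROUP}}


def evaluate_external(checkpoint, data_dir, out_dir=None,
                      test_scan: str | None = None, net=None,
                      split: SplitPlan | None = None,
                      tile: int | None = None) -> dict:
    """Run held-out inference and compute the full metric suite.

    ``checkpoint`` may be a path (the stored split is then used for the
    leakage check) or None when ``net`` and ``split`` are passed directly.
    Writes tidy metrics CSV, a JSON summary and overlay images when
    ``out_dir`` is given.
    """
    if net is None:
        net, meta = load_checkpoint(checkpoint)
        if tile is None:
            tile = meta["extra"].get("infer_tile")
        if split is None and meta["extra"].get("split"):
            split = SplitPlan(**{k: tuple(v) for k, v
                                 in meta["extra"]["split"].items()})
    if split is not None and test_scan is None:
        test_scan = split.test_scans[0]
    if test_scan is None:
        raise ValueError("no test scan specified")
    if split is not None and test_scan in split.train_scans:
        raise LeakageError(
            f"scan {test_scan!r} was in the training partition")

    blind = net.config.variant == "blind_control"
    scans = load_dataset(data_dir, blind=blind)
    sc = scans[test_scan]
    pred = predict_volume(net, sc["values"], tile=tile)
    table = metric_table(pred, sc["labels"])
    summary = macro_average(table)
    series = slice_error_series(table, class_groups())

    result = {"test_scan": test_scan, "table": table, "macro": summary,
              "error_series": series, "predictions": pred}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"metrics_{test_scan}.csv", index=False)
        with open(out_dir / f"summary_{test_scan}.json", "w") as fh:
            json.dump({"test_scan": test_scan,
                       "macro": summary["macro"],
                       "per_class": {m: {str(k): v for k, v in d.items()}
                                     for m, d in summary["per_class"].items()},
                       "present_classes": summary["present_classes"]},
                      fh, indent=2)
        from .viz import render_error_band_plot, render_overlay
        raw = load_scan(Path(data_dir) / f"{test_scan}.npz")[0]
        mid = raw.values.shape[0] // 2
        render_overlay(raw.values[mid], pred[mid],
                       out_dir / f"overlay_{test_scan}_pred.png")
        render_overlay(raw.values[mid], sc["labels"][mid],
                       out_dir / f"overlay_{test_scan}_gt.png")
        for gname, rec in series.items():
            render_error_band_plot(
                rec, out_dir / f"error_band_{test_scan}_{gname}.png",
                title=f"{gname}: slice-wise Dice error")
    return result


def run_ablation(variants, protocol: TrainProtocol, split: SplitPlan,
                 data_dir, seeds, base_config: NetworkConfig | None = None,
                 out_dir=None, verbose: bool = False) -> pd.DataFrame:
    """Train every (variant, seed) under one shared protocol and summarize.

    Returns one row per variant (fixed plain-to-full order) with macro
    Dice/Sensitivity/Specificity/Precision/IoU as mean and SD over seeds.
    """
    order = [v for v in ("plain", "sp", "e_sp", "fg_sp", "spff",
                         "blind_control") if v in set(variants)]
    unknown = set(variants) - set(order)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    if base_config is None:
        base_config = NetworkConfig()
    rows = []
    for variant in order:
        cfg = replace(base_config, variant=variant)
        per_seed = {m: [] for m in
                    ("dice", "sensitivity", "specificity", "precision", "iou")}
        for seed in seeds:
            _, _, net = train_model(cfg, protocol, split, data_dir, seed,
                                    out_dir=out_dir, verbose=verbose)
            res = evaluate_external(None, data_dir, net=net, split=split)
            for m in per_seed:
                per_seed[m].append(res["macro"]["macro"][m])
        row = {"variant": variant}
        for m, vals in per_seed.items():
            mean, sd = aggregate_seeds(vals)
            row[f"{m}_mean"], row[f"{m}_sd"] = mean, sd
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "ablation.csv", index=False)
    return df
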