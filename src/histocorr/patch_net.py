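"""First-stage patch classifier: a residual CNN trained with class-weighted
cross-entropy on weakly labeled tumor patches.

The same trained network serves two purposes downstream: it emits per-patch
positive-class posteriors (independent patch classification) and per-patch
feature vectors (global-average-pooled activations of the last residual
stage) that the region-correlation stage reassembles spatially.

Class weights are inverse to the class frequencies, w_c = N / (2 * n_c),
i.e. normalized so the mean per-example weight is one; with these weights
each class contributes equally to the expected loss of a prior-probability
predictor regardless of imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .evaluation import roc_auc
from .preprocess import AugmentConfig, eval_transform, train_transform
from .tiling import PatchRecord

__all__ = [
    "BackboneConfig",
    "ClassWeights",
    "PatchTrainConfig",
    "PatchDataset",
    "compute_class_weights",
    "build_backbone",
    "train_patch_classifier",
    "predict_patch_probabilities",
    "extract_patch_features",
    "PatchModelBundle",
]

_PRESET_WIDTH = {"resnet18": 1.0, "resnet18_slim": 0.25}


@dataclass
class BackboneConfig:
    preset: str = "resnet18"
    width_multiplier: float | None = None   # None -> preset default
    pretrained_weights: str | None = None   # optional .npz state dict
    seed: int = 0

    def __post_init__(self):
        if self.preset not in _PRESET_WIDTH:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(_PRESET_WIDTH)}")
        if self.width_multiplier is None:
            self.width_multiplier = _PRESET_WIDTH[self.preset]

    @property
    def feature_dim(self) -> int:
        return max(4, int(round(512 * self.width_multiplier)))


@dataclass(frozen=True)
class ClassWeights:
    w_pos: float
    w_neg: float

    def as_array(self) -> np.ndarray:
        """Index 0 = negative class, index 1 = positive class."""
        return np.array([self.w_neg, self.w_pos], dtype=np.float64)


@dataclass
class PatchTrainConfig:
    epochs: int = 30
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 64
    lr_milestones: tuple[int, ...] = (10, 20)
    lr_gamma: float = 0.2
    seed: int = 0
    checkpoint_metric: str = "val_auc"


def compute_class_weights(n_pos: int, n_neg: int) -> ClassWeights:
    """Inverse-frequency weights normalized to mean one:
    w_pos = N/(2*n_pos), w_neg = N/(2*n_neg)."""
    if n_pos + n_neg <= 0:
        raise ValueError("need at least one training example")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate training set: one class has zero examples")
    n = n_pos + n_neg
    return ClassWeights(w_pos=n / (2.0 * n_pos), w_neg=n / (2.0 * n_neg))


@dataclass
class PatchDataset:
    """In-memory patch collection: pixels, weak labels and source slides."""

    pixels: np.ndarray            # (N, side, side, 3) uint8
    labels: np.ndarray            # (N,) int 0/1
    slide_ids: list[str] = field(default_factory=list)
    grid_cells: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_records(cls, records: list[PatchRecord]) -> "PatchDataset":
        if not records:
            raise ValueError("no patch records")
        return cls(
            pixels=np.stack([r.pixels for r in records]),
            labels=np.array([r.y for r in records], dtype=np.int64),
            slide_ids=[r.slide_id for r in records],
            grid_cells=[(r.grid_row, r.grid_col) for r in records])

    def __len__(self) -> int:
        return len(self.labels)


def build_backbone(cfg: BackboneConfig) -> nn.ResNet18:
    model = nn.ResNet18(width_multiplier=cfg.width_multiplier, seed=cfg.seed)
    if cfg.pretrained_weights:
        state = dict(np.load(cfg.pretrained_weights))
        nn.set_state(model, state)
    return model


def _to_net_input(batch_uint8: np.ndarray) -> np.ndarray:
    """uint8 NHWC -> standardized float32 NCHW."""
    x = batch_uint8.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _check_disjoint(train_ids, val_ids):
    overlap = sorted(set(train_ids) & set(val_ids))
    if overlap:
        raise ValueError(
            "information leakage: slides present in both train and validation "
            f"sets: {overlap}")


@dataclass
class PatchModelBundle:
    model: nn.ResNet18
    backbone: BackboneConfig
    class_weights: ClassWeights
    history: pd.DataFrame
    crop_px: int
    best_val_auc: float

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **nn.get_state(self.model))
        self.history.to_csv(out / "history.csv", index=False)
        meta = {"preset": self.backbone.preset,
                "width_multiplier": self.backbone.width_multiplier,
                "seed": self.backbone.seed,
                "crop_px": self.crop_px,
                "w_pos": self.class_weights.w_pos,
                "w_neg": self.class_weights.w_neg,
                "best_val_auc": self.best_val_auc}
        (out / "config.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, out_dir: str | Path) -> "PatchModelBundle":
        out = Path(out_dir)
        meta = yaml.safe_load((out / "config.yaml").read_text())
        backbone = BackboneConfig(preset=meta["preset"],
                                  width_multiplier=meta["width_multiplier"],
                                  seed=meta["seed"])
        model = build_backbone(backbone)
        nn.set_state(model, dict(np.load(out / "weights.npz")))
        history = pd.read_csv(out / "history.csv") if (out / "history.csv").exists() \
            else pd.DataFrame()
        return cls(model=model, backbone=backbone,
                   class_weights=ClassWeights(meta["w_pos"], meta["w_neg"]),
                   history=history, crop_px=int(meta["crop_px"]),
                   best_val_auc=float(meta["best_val_auc"]))


def train_patch_classifier(train_ds: PatchDataset, val_ds: PatchDataset,
                           backbone: BackboneConfig, cfg: PatchTrainConfig,
                           augment: AugmentConfig | None = None) -> PatchModelBundle:
    """Train the patch classifier; returns the bundle holding the checkpoint
    with the best validation AUC and the per-epoch history table."""
    _check_disjoint(train_ds.slide_ids, val_ds.slide_ids)
    augment = augment or AugmentConfig()
    weights = compute_class_weights(int(train_ds.labels.sum()),
                                    int((1 - train_ds.labels).sum()))
    w_arr = weights.as_array()
    model = build_backbone(backbone)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best_auc, best_state = -np.inf, None
    n = len(train_ds)
    for epoch in range(cfg.epochs):
        lr = nn.step_lr(cfg.lr, epoch, cfg.lr_milestones, cfg.lr_gamma)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = np.stack([train_transform(train_ds.pixels[i], augment, rng)
                              for i in idx])
            x = _to_net_input(batch)
            logits = model.forward(x, train=True)
            loss, dlogits = nn.weighted_softmax_cross_entropy(
                logits, train_ds.labels[idx], w_arr)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_probs = predict_patch_probabilities(model, val_ds.pixels,
                                                crop_px=augment.crop_px,
                                                batch_size=cfg.batch_size)
        val_auc = roc_auc(val_probs, val_ds.labels) \
            if val_ds.labels.min() != val_ds.labels.max() else float("nan")
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": float(np.mean(losses)),
                        "val_auc": val_auc})
        if np.isnan(val_auc):
            best_auc, best_state = val_auc, nn.get_state(model)
        elif val_auc > best_auc or best_state is None:
            best_auc, best_state = val_auc, nn.get_state(model)
    nn.set_state(model, best_state)
    return PatchModelBundle(model=model, backbone=backbone, class_weights=weights,
                            history=pd.DataFrame(history), crop_px=augment.crop_px,
                            best_val_auc=float(best_auc))


def _iter_batches(pixels: np.ndarray, crop_px: int, batch_size: int):
    crops = np.stack([eval_transform(p, crop_px) for p in pixels])
    for start in range(0, len(crops), batch_size):
        yield _to_net_input(crops[start:start + batch_size])


def predict_patch_probabilities(model: nn.ResNet18, pixels: np.ndarray,
                                crop_px: int, batch_size: int = 64) -> np.ndarray:
    """Positive-class posterior per patch (softmax of the final layer);
    patches are center-cropped with the evaluation transform first."""
    probs = []
    for x in _iter_batches(pixels, crop_px, batch_size):
        logits = model.forward(x, train=False)
        probs.append(nn.softmax(logits)[:, 1])
    return np.concatenate(probs)


def extract_patch_features(model: nn.ResNet18, pixels: np.ndarray,
                           crop_px: int, batch_size: int = 64) -> np.ndarray:
    """Per-patch feature vectors: global-average-pooled activations of the
    final residual stage (length = model.feature_dim)."""
    feats = []
    for x in _iter_batches(pixels, crop_px, batch_size):
        feats.append(model.features(x, train=False))
    return np.concatenate(feats)
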