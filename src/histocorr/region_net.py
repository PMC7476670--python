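"""Region-correlation stage: reassemble per-patch feature vectors into a
per-slide global feature map and refine them with an encoder-decoder.

Neighboring tumor patches tend to share class status; an encoder-decoder run
over the spatially reassembled feature map can exploit that correlation,
which an independent per-patch classifier cannot. The network outputs one
logit per grid cell; the logistic transform followed by an element-wise
product with the tumor-cell mask yields the probability map (exactly zero
off-tumor). Training uses a mask-gated class-weighted cross-entropy: every
tumor cell of a slide carries the slide's label, off-mask cells contribute
exactly zero to loss and gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .evaluation import roc_auc, slide_probability
from .patch_net import ClassWeights, compute_class_weights
from .tiling import PatchGrid

__all__ = [
    "GlobalFeatureMap",
    "ProbabilityMap",
    "UNetConfig",
    "RegionTrainConfig",
    "assemble_global_features",
    "masked_weighted_cross_entropy",
    "train_region_model",
    "predict_probability_map",
    "RegionModelBundle",
]


@dataclass
class GlobalFeatureMap:
    slide_id: str
    features: np.ndarray      # (H, W, C) float32, zero at non-tumor cells
    tumor_cells: np.ndarray   # (H, W) uint8
    pad_info: tuple[int, int, int, int]   # (top, bottom, left, right)

    @property
    def grid_shape(self) -> tuple[int, int]:
        t, b, l, r = self.pad_info
        return (self.features.shape[0] - t - b, self.features.shape[1] - l - r)


@dataclass
class ProbabilityMap:
    slide_id: str
    probs: np.ndarray         # (H, W) in [0,1], exactly 0 off-tumor
    tumor_cells: np.ndarray   # (H, W) uint8


@dataclass
class UNetConfig:
    depth: int = 2
    base_channels: int = 16
    in_channels: int = 128
    batch_norm: bool = True
    seed: int = 0


@dataclass
class RegionTrainConfig:
    epochs: int = 100
    lr: float = 0.0001        # constant across epochs
    momentum: float = 0.9
    weight_decay: float = 0.0005
    seed: int = 0
    # random flips/transposes of the (feature map, mask) pair per step;
    # label-preserving spatial augmentation that matters when only tens of
    # training slides exist
    augment_flips: bool = False
    # "slide_auc": AUC of mean map posteriors over validation slides;
    # "cell_auc": AUC over validation tumor cells vs the weak slide labels
    # (far less granular-noise-prone when only a handful of validation
    # slides exist, as in scaled-down runs).
    checkpoint_metric: str = "slide_auc"


def assemble_global_features(patch_features: dict[tuple[int, int], np.ndarray],
                             grid: PatchGrid, depth: int = 2,
                             slide_id: str | None = None) -> GlobalFeatureMap:
    """Place per-patch feature vectors at their grid cells, zero elsewhere,
    then zero-pad symmetrically (extra row/col on the bottom/right when odd)
    until both spatial dims divide 2**depth."""
    occupied = [cell for cell, _ in grid.cell_index.items()]
    missing = sorted(set(occupied) - set(patch_features))
    if missing:
        raise ValueError(f"missing feature vectors for occupied cells: {missing}")
    hg, wg = grid.grid_shape
    if occupied:
        c = len(np.asarray(patch_features[occupied[0]]).ravel())
    else:
        c = len(next(iter(patch_features.values()))) if patch_features else 1
    feats = np.zeros((hg, wg, c), dtype=np.float32)
    for cell in occupied:
        feats[cell] = np.asarray(patch_features[cell], dtype=np.float32)
    m = 2 ** depth
    pad_h = (-hg) % m
    pad_w = (-wg) % m
    top, left = pad_h // 2, pad_w // 2
    bottom, right = pad_h - top, pad_w - left
    feats = np.pad(feats, ((top, bottom), (left, right), (0, 0)))
    cells = np.pad(grid.tumor_cells.astype(np.uint8),
                   ((top, bottom), (left, right)))
    return GlobalFeatureMap(slide_id=slide_id or grid.slide_id, features=feats,
                            tumor_cells=cells, pad_info=(top, bottom, left, right))


def masked_weighted_cross_entropy(prob_map: np.ndarray, label: int,
                                  tumor_cells: np.ndarray,
                                  weights: ClassWeights | None = None,
                                  eps: float = 1e-12) -> float:
    """loss = sum_{tumor cells} w_label * CE(p, label) / sum_{tumor cells} w_label.

    ``prob_map`` holds pre-mask probabilities; off-mask cells contribute
    exactly zero. An all-zero mask returns 0.0 with a warning (the slide is
    skipped in training).
    """
    p = np.asarray(prob_map, dtype=np.float64)
    mask = np.asarray(tumor_cells) != 0
    if p.shape != mask.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs mask {mask.shape}")
    if not mask.any():
        warnings.warn("tumor mask is all zero; loss is 0 and the slide is skipped")
        return 0.0
    y = 1 if label in (1, "POS", True) else 0
    w = 1.0 if weights is None else (weights.w_pos if y else weights.w_neg)
    pm = np.clip(p[mask], eps, 1 - eps)
    ce = -(y * np.log(pm) + (1 - y) * np.log(1 - pm))
    return float((w * ce).sum() / (w * mask.sum()))


def cell_class_weights(items) -> ClassWeights:
    """Inverse-frequency weights from tumor-cell counts of the training
    slides (each tumor cell carries its slide's label)."""
    n_pos = sum(int(g.tumor_cells.sum()) for g, lab in items
                if lab in (1, "POS", True))
    n_neg = sum(int(g.tumor_cells.sum()) for g, lab in items
                if lab not in (1, "POS", True))
    return compute_class_weights(n_pos, n_neg)


@dataclass
class RegionModelBundle:
    model: nn.UNet
    config: UNetConfig
    class_weights: ClassWeights
    history: pd.DataFrame
    best_val_auc: float

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **nn.get_state(self.model))
        self.history.to_csv(out / "history.csv", index=False)
        meta = {"depth": self.config.depth,
                "base_channels": self.config.base_channels,
                "in_channels": self.config.in_channels,
                "batch_norm": self.config.batch_norm,
                "seed": self.config.seed,
                "w_pos": self.class_weights.w_pos,
                "w_neg": self.class_weights.w_neg,
                "best_val_auc": self.best_val_auc}
        (out / "config.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, out_dir: str | Path) -> "RegionModelBundle":
        out = Path(out_dir)
        meta = yaml.safe_load((out / "config.yaml").read_text())
        cfg = UNetConfig(depth=meta["depth"], base_channels=meta["base_channels"],
                         in_channels=meta["in_channels"],
                         batch_norm=meta.get("batch_norm", True), seed=meta["seed"])
        model = nn.UNet(in_channels=cfg.in_channels,
                        base_channels=cfg.base_channels, depth=cfg.depth,
                        seed=cfg.seed, batch_norm=cfg.batch_norm)
        nn.set_state(model, dict(np.load(out / "weights.npz")))
        history = pd.read_csv(out / "history.csv") if (out / "history.csv").exists() \
            else pd.DataFrame()
        return cls(model=model, config=cfg,
                   class_weights=ClassWeights(meta["w_pos"], meta["w_neg"]),
                   history=history, best_val_auc=float(meta["best_val_auc"]))


def _forward_map(model: nn.UNet, gmap: GlobalFeatureMap, train: bool):
    if gmap.features.shape[2] != model.in_channels:
        raise ValueError(
            f"feature channels {gmap.features.shape[2]} != model input "
            f"channels {model.in_channels}")
    x = np.ascontiguousarray(
        gmap.features.transpose(2, 0, 1)[None]).astype(np.float32)
    return model.forward(x, train=train)[0]


def train_region_model(train_items, val_items, unet: UNetConfig,
                       cfg: RegionTrainConfig) -> RegionModelBundle:
    """Train the encoder-decoder on per-slide global feature maps.

    ``train_items`` / ``val_items``: lists of (GlobalFeatureMap, label).
    One slide per optimization step (grids vary in size); the checkpoint with
    the best validation slide-level AUC is returned. The feature extractor is
    frozen by construction (features are precomputed).
    """
    train_ids = [g.slide_id for g, _ in train_items]
    val_ids = [g.slide_id for g, _ in val_items]
    overlap = sorted(set(train_ids) & set(val_ids))
    if overlap:
        raise ValueError(f"information leakage: slides in both train and "
                         f"validation sets: {overlap}")
    for g, _ in list(train_items) + list(val_items):
        if g.features.shape[2] != unet.in_channels:
            raise ValueError(
                f"slide {g.slide_id}: feature channels {g.features.shape[2]} "
                f"!= unet.in_channels {unet.in_channels}")
    weights = cell_class_weights(train_items)
    model = nn.UNet(in_channels=unet.in_channels, base_channels=unet.base_channels,
                    depth=unet.depth, seed=unet.seed, batch_norm=unet.batch_norm)
    # fixed input standardization from training tumor-cell features
    cell_feats = [g.features[g.tumor_cells != 0] for g, _ in train_items
                  if g.tumor_cells.any()]
    if cell_feats:
        allf = np.concatenate(cell_feats, axis=0)
        model.set_input_stats(allf.mean(axis=0), allf.std(axis=0))
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best_auc, best_state = -np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_items))
        losses = []
        for i in order:
            gmap, label = train_items[i]
            if not gmap.tumor_cells.any():
                continue
            y = 1 if label in (1, "POS", True) else 0
            feats, cells = gmap.features, gmap.tumor_cells
            if cfg.augment_flips:
                if rng.random() < 0.5:
                    feats, cells = feats[::-1], cells[::-1]
                if rng.random() < 0.5:
                    feats, cells = feats[:, ::-1], cells[:, ::-1]
                if feats.shape[0] == feats.shape[1] and rng.random() < 0.5:
                    feats = feats.transpose(1, 0, 2)
                    cells = cells.T
            x = np.ascontiguousarray(feats.transpose(2, 0, 1)[None]).astype(np.float32)
            logits = model.forward(x, train=True)[0]
            w = weights.w_pos if y else weights.w_neg
            loss, dlogits = nn.bce_with_logits_map(
                logits, float(y), cells, weight=w)
            opt.zero_grad()
            model.backward(dlogits[None])
            opt.step()
            losses.append(loss)
        val_auc = _validation_auc(model, val_items, cfg.checkpoint_metric)
        history.append({"epoch": epoch, "lr": cfg.lr,
                        "train_loss": float(np.mean(losses)) if losses else np.nan,
                        "val_auc": val_auc})
        if np.isnan(val_auc):
            best_auc, best_state = val_auc, nn.get_state(model)
        elif val_auc > best_auc or best_state is None:
            best_auc, best_state = val_auc, nn.get_state(model)
    nn.set_state(model, best_state)
    return RegionModelBundle(model=model, config=unet, class_weights=weights,
                             history=pd.DataFrame(history),
                             best_val_auc=float(best_auc))


def _validation_auc(model: nn.UNet, val_items, metric: str = "slide_auc") -> float:
    """Validation AUC: slide level (mean map posterior per slide) or tumor-
    cell level against the weak slide labels."""
    scores, labels = [], []
    for gmap, label in val_items:
        pmap = predict_probability_map(model, gmap)
        y = 1 if label in (1, "POS", True) else 0
        if metric == "slide_auc":
            scores.append(slide_probability(pmap))
            labels.append(y)
        elif metric == "cell_auc":
            cells = pmap.probs[pmap.tumor_cells != 0]
            scores.extend(cells)
            labels.extend([y] * cells.size)
        else:
            raise ValueError(f"unknown checkpoint metric {metric!r}")
    if len(set(labels)) < 2:
        return float("nan")
    return roc_auc(scores, labels)


def predict_probability_map(model: nn.UNet, gmap: GlobalFeatureMap) -> ProbabilityMap:
    """Logistic output per cell, multiplied element-wise by the tumor-cell
    mask (exactly 0 off-tumor), with the assembly padding removed."""
    logits = _forward_map(model, gmap, train=False)
    probs = nn.sigmoid(logits) * (gmap.tumor_cells != 0)
    top, bottom, left, right = gmap.pad_info
    h, w = probs.shape
    sl = np.s_[top:h - bottom, left:w - right]
    return ProbabilityMap(slide_id=gmap.slide_id,
                          probs=probs[sl].astype(np.float64),
                          tumor_cells=gmap.tumor_cells[sl].copy())
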