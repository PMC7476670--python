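"""End-to-end experiment orchestration.

Protocol: synthesize (or load) a training cohort and a test cohort from a
different scanner domain -> tumor-masked tiling -> stratified slide-level
K-fold split -> per fold, train the patch classifier, cache its features,
assemble global feature maps and train the region model -> evaluate each
model and the K-model ensemble at patch and slide level on the held-out
test cohort.

Every stage seed is derived deterministically from the experiment seed, and
a run manifest (config hash, seeds, package version) makes outputs
attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (ensemble_average, evaluate_scores, make_slide_folds,
                         render_probability_map, slide_probability)
from .patch_net import (BackboneConfig, PatchDataset, PatchTrainConfig,
                        extract_patch_features, predict_patch_probabilities,
                        train_patch_classifier)
from .preprocess import AugmentConfig
from .region_net import (RegionTrainConfig, UNetConfig,
                         assemble_global_features, predict_probability_map,
                         train_region_model)
from .synthetic import SlideRecord, SyntheticSpec, generate_cohort
from .tiling import tile_slide

__all__ = [
    "SynthBlock", "TileBlock", "ExperimentConfig", "desk_scale_config",
    "tile_cohort", "run_cross_validation", "evaluate_on_test",
    "run_experiment", "region_gain_experiment",
]


@dataclass
class SynthBlock:
    n_pos_train: int = 16
    n_neg_train: int = 16
    n_pos_test: int = 4
    n_neg_test: int = 4
    slide_px: int = 512
    tile_px: int = 64
    heterogeneity_rate: float = 0.3
    heterogeneity_smoothness: float = 3.0
    train_domain: str = "aperio"
    test_domain: str = "ventana"


@dataclass
class TileBlock:
    patch_dim: int = 64
    min_tumor_ratio: float = 0.9
    resize_to: int = 64


@dataclass
class ExperimentConfig:
    seed: int = 0
    k_folds: int = 5
    synth: SynthBlock = field(default_factory=SynthBlock)
    tile: TileBlock = field(default_factory=TileBlock)
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(crop_px=56))
    backbone: BackboneConfig = field(
        default_factory=lambda: BackboneConfig(preset="resnet18_slim"))
    patch_train: PatchTrainConfig = field(
        default_factory=lambda: PatchTrainConfig(epochs=5, batch_size=32))
    # Desk-scale region stage: plain conv blocks (batch statistics from a
    # single small map are unreliable), a larger constant rate than the
    # reference 1e-4 (which suits the long-schedule large-cohort regime;
    # here the optimizer takes only ~750 steps), label-preserving flip
    # augmentation of the feature maps, and checkpointing on the (much less
    # granular-noise-prone) cell-level AUC.
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(batch_norm=False))
    region_train: RegionTrainConfig = field(
        default_factory=lambda: RegionTrainConfig(
            epochs=30, lr=0.003, checkpoint_metric="cell_auc",
            augment_flips=True))
    eval_n_boot: int = 500
    eval_alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "ExperimentConfig":
        text = Path(path_or_text).read_text() \
            if isinstance(path_or_text, Path) or "\n" not in str(path_or_text) \
            else str(path_or_text)
        data = yaml.safe_load(text) or {}
        kwargs = {}
        blocks = {"synth": SynthBlock, "tile": TileBlock, "augment": AugmentConfig,
                  "backbone": BackboneConfig, "patch_train": PatchTrainConfig,
                  "unet": UNetConfig, "region_train": RegionTrainConfig}
        for key, val in data.items():
            if key in blocks:
                if key == "patch_train" and "lr_milestones" in val:
                    val["lr_milestones"] = tuple(val["lr_milestones"])
                kwargs[key] = blocks[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def desk_scale_config(seed: int = 0) -> ExperimentConfig:
    """The default CPU-scale experiment: 40 synthetic slides (20 pos / 20
    neg; 32 train from one scanner domain, 8 test from the other), 512-px
    slides with 64-px tiles kept at native resolution, heterogeneity rate
    0.3 with 3-tile correlation length, 5-fold CV with the quarter-width
    backbone and a depth-2 region model."""
    return ExperimentConfig(seed=seed)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s & 0x7FFFFFFF)
            for s in np.random.SeedSequence(seed).generate_state(n)]


def tile_cohort(records: list[SlideRecord], tile: TileBlock,
                allow_upscale: bool = True) -> dict:
    """Tile every slide; returns {slide_id: (PatchGrid, [PatchRecord])}."""
    return {rec.slide_id: tile_slide(rec, tile.patch_dim,
                                     min_tumor_ratio=tile.min_tumor_ratio,
                                     resize_to=tile.resize_to,
                                     allow_upscale=allow_upscale)
            for rec in records}


def _dataset_for(slide_ids, tiled, labels) -> PatchDataset:
    records = []
    for sid in slide_ids:
        _, patches = tiled[sid]
        records.extend(patches)
    return PatchDataset.from_records(records)


def _global_maps(bundle, slide_ids, tiled, depth: int):
    """Feature extraction + reassembly for a set of slides."""
    maps = {}
    for sid in slide_ids:
        grid, patches = tiled[sid]
        if not patches:
            continue
        pixels = np.stack([p.pixels for p in patches])
        feats = extract_patch_features(bundle.model, pixels, bundle.crop_px)
        per_cell = {(p.grid_row, p.grid_col): feats[i]
                    for i, p in enumerate(patches)}
        maps[sid] = assemble_global_features(per_cell, grid, depth=depth)
    return maps


@dataclass
class CVRun:
    config: ExperimentConfig
    fold_split: object
    patch_bundles: list
    region_bundles: list
    train_records: list
    tiled_train: dict
    labels: dict[str, str]


def run_cross_validation(cfg: ExperimentConfig,
                         train_records: list[SlideRecord] | None = None) -> CVRun:
    seeds = _spawn_seeds(cfg.seed, 8)
    if train_records is None:
        spec = SyntheticSpec(slide_px=cfg.synth.slide_px, tile_px=cfg.synth.tile_px,
                             heterogeneity_rate=cfg.synth.heterogeneity_rate,
                             heterogeneity_smoothness=cfg.synth.heterogeneity_smoothness)
        train_records, _ = generate_cohort(
            cfg.synth.n_pos_train, cfg.synth.n_neg_train, spec,
            domain=cfg.synth.train_domain, seed=seeds[0], id_prefix="tr")
    labels = {r.slide_id: r.label for r in train_records}
    manifest = pd.DataFrame({"slide_id": list(labels), "label": list(labels.values())})
    fold_split = make_slide_folds(manifest, k=cfg.k_folds, seed=seeds[1])
    tiled = tile_cohort(train_records, cfg.tile)
    patch_bundles, region_bundles = [], []
    for fold, train_ids, val_ids in fold_split.rotations():
        train_ds = _dataset_for(train_ids, tiled, labels)
        val_ds = _dataset_for(val_ids, tiled, labels)
        backbone = dataclasses.replace(cfg.backbone, seed=seeds[2] + fold)
        ptrain = dataclasses.replace(cfg.patch_train, seed=seeds[3] + fold)
        bundle = train_patch_classifier(train_ds, val_ds, backbone, ptrain,
                                        augment=cfg.augment)
        patch_bundles.append(bundle)
        unet = dataclasses.replace(cfg.unet,
                                   in_channels=bundle.backbone.feature_dim,
                                   seed=seeds[4] + fold)
        rtrain = dataclasses.replace(cfg.region_train, seed=seeds[5] + fold)
        gmaps = _global_maps(bundle, train_ids + val_ids, tiled, unet.depth)
        train_items = [(gmaps[s], labels[s]) for s in train_ids if s in gmaps]
        val_items = [(gmaps[s], labels[s]) for s in val_ids if s in gmaps]
        region_bundles.append(train_region_model(train_items, val_items,
                                                 unet, rtrain))
    return CVRun(config=cfg, fold_split=fold_split, patch_bundles=patch_bundles,
                 region_bundles=region_bundles, train_records=train_records,
                 tiled_train=tiled, labels=labels)


def _test_scores(cv: CVRun, test_records: list[SlideRecord]):
    """Per-model and ensemble patch/slide scores on a held-out cohort."""
    cfg = cv.config
    train_ids = set(cv.labels)
    overlap = sorted(train_ids & {r.slide_id for r in test_records})
    if overlap:
        raise ValueError(f"test slides overlap training slides: {overlap}")
    tiled = tile_cohort(test_records, cfg.tile)
    slide_ids = [r.slide_id for r in test_records if tiled[r.slide_id][1]]
    slide_labels = [r.label for r in test_records if tiled[r.slide_id][1]]
    patch_labels = []
    patch_slide = []
    for sid in slide_ids:
        _, patches = tiled[sid]
        patch_labels.extend(p.y for p in patches)
        patch_slide.extend(sid for _ in patches)
    per_model = {"independent": [], "region": []}
    for pb, rb in zip(cv.patch_bundles, cv.region_bundles):
        indep, region = [], []
        for sid in slide_ids:
            grid, patches = tiled[sid]
            pixels = np.stack([p.pixels for p in patches])
            indep.extend(predict_patch_probabilities(pb.model, pixels, pb.crop_px))
            feats = extract_patch_features(pb.model, pixels, pb.crop_px)
            per_cell = {(p.grid_row, p.grid_col): feats[i]
                        for i, p in enumerate(patches)}
            gmap = assemble_global_features(per_cell, grid,
                                            depth=rb.config.depth)
            pmap = predict_probability_map(rb.model, gmap)
            region.extend(pmap.probs[p.grid_row, p.grid_col] for p in patches)
        per_model["independent"].append(np.asarray(indep))
        per_model["region"].append(np.asarray(region))
    return {
        "tiled": tiled,
        "slide_ids": slide_ids,
        "slide_labels": slide_labels,
        "patch_labels": np.asarray(patch_labels),
        "patch_slide": patch_slide,
        "per_model": per_model,
    }


def _slide_means(patch_scores, patch_slide, slide_ids):
    s = pd.Series(patch_scores, index=pd.Index(patch_slide, name="slide_id"))
    means = s.groupby(level=0).mean()
    return np.asarray([means[sid] for sid in slide_ids])


def evaluate_on_test(cv: CVRun, test_records: list[SlideRecord],
                     seed: int = 0) -> dict:
    """Patch- and slide-level reports for each variant (independent, region)
    per model and for the K-model ensemble."""
    cfg = cv.config
    sc = _test_scores(cv, test_records)
    reports = []
    scores = {}
    for variant in ("independent", "region"):
        model_scores = sc["per_model"][variant]
        ens = ensemble_average(model_scores)
        for name, patch_scores in ([(f"model-{i+1}", m)
                                    for i, m in enumerate(model_scores)]
                                   + [("ensemble", ens)]):
            slide_scores = _slide_means(patch_scores, sc["patch_slide"],
                                        sc["slide_ids"])
            rep_p = evaluate_scores(patch_scores, sc["patch_labels"],
                                    n_boot=cfg.eval_n_boot, alpha=cfg.eval_alpha,
                                    seed=seed)
            rep_s = evaluate_scores(slide_scores, sc["slide_labels"],
                                    n_boot=cfg.eval_n_boot, alpha=cfg.eval_alpha,
                                    seed=seed)
            row_p = rep_p.as_row("patch", variant); row_p["model"] = name
            row_s = rep_s.as_row("slide", variant); row_s["model"] = name
            reports.extend([row_p, row_s])
            scores[(variant, name)] = {"patch": patch_scores,
                                       "slide": slide_scores}
    return {"reports": pd.DataFrame(reports), "scores": scores, **sc}


def run_experiment(cfg: ExperimentConfig, workdir: str | Path | None = None,
                   render_slides: int = 0) -> dict:
    """Full protocol; returns the CV run, test evaluation and run manifest."""
    seeds = _spawn_seeds(cfg.seed, 8)
    cv = run_cross_validation(cfg)
    spec = SyntheticSpec(slide_px=cfg.synth.slide_px, tile_px=cfg.synth.tile_px,
                         heterogeneity_rate=cfg.synth.heterogeneity_rate,
                         heterogeneity_smoothness=cfg.synth.heterogeneity_smoothness)
    test_records, _ = generate_cohort(
        cfg.synth.n_pos_test, cfg.synth.n_neg_test, spec,
        domain=cfg.synth.test_domain, seed=seeds[6], id_prefix="te")
    test_eval = evaluate_on_test(cv, test_records, seed=seeds[7])
    run_manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "histocorr_version": __version__,
        "n_train_slides": len(cv.train_records),
        "n_test_slides": len(test_records),
    }
    if workdir is not None:
        out = Path(workdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg.to_yaml())
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
        test_eval["reports"].to_csv(out / "reports.csv", index=False)
        for i, (pb, rb) in enumerate(zip(cv.patch_bundles, cv.region_bundles)):
            pb.save(out / f"model-{i+1}" / "patch")
            rb.save(out / f"model-{i+1}" / "region")
        for rec in test_records[:render_slides]:
            grid, patches = test_eval["tiled"][rec.slide_id]
            if not patches:
                continue
            pixels = np.stack([p.pixels for p in patches])
            pb, rb = cv.patch_bundles[0], cv.region_bundles[0]
            feats = extract_patch_features(pb.model, pixels, pb.crop_px)
            per_cell = {(p.grid_row, p.grid_col): feats[i]
                        for i, p in enumerate(patches)}
            gmap = assemble_global_features(per_cell, grid, depth=rb.config.depth)
            pmap = predict_probability_map(rb.model, gmap)
            render_probability_map(pmap, out / f"{rec.slide_id}_region_map.png")
    return {"cv": cv, "test_records": test_records, "test_eval": test_eval,
            "run_manifest": run_manifest}


def region_gain_experiment(seed: int = 0, n_pos: int = 12, n_neg: int = 12,
                           patch_epochs: int = 5, region_epochs: int = 30) -> dict:
    """Single-split comparison of region-correlation vs independent patch
    classification on a spatially-heterogeneous cohort (rate 0.3,
    correlation length 3 tiles). Returns validation patch-level AUCs of
    both variants against the weak slide labels."""
    cfg = desk_scale_config(seed)
    seeds = _spawn_seeds(seed, 6)
    spec = SyntheticSpec(slide_px=cfg.synth.slide_px, tile_px=cfg.synth.tile_px,
                         heterogeneity_rate=0.3, heterogeneity_smoothness=3.0)
    records, _ = generate_cohort(n_pos, n_neg, spec, domain="aperio",
                                 seed=seeds[0], id_prefix="g")
    labels = {r.slide_id: r.label for r in records}
    manifest = pd.DataFrame({"slide_id": list(labels), "label": list(labels.values())})
    folds = make_slide_folds(manifest, k=3, seed=seeds[1])
    _, train_ids, val_ids = folds.rotations()[0]
    tiled = tile_cohort(records, cfg.tile)
    train_ds = _dataset_for(train_ids, tiled, labels)
    val_ds = _dataset_for(val_ids, tiled, labels)
    backbone = dataclasses.replace(cfg.backbone, seed=seeds[2])
    ptrain = dataclasses.replace(cfg.patch_train, epochs=patch_epochs, seed=seeds[3])
    bundle = train_patch_classifier(train_ds, val_ds, backbone, ptrain,
                                    augment=cfg.augment)
    unet = dataclasses.replace(cfg.unet, in_channels=backbone.feature_dim,
                               seed=seeds[4])
    rtrain = dataclasses.replace(cfg.region_train, epochs=region_epochs,
                                 seed=seeds[5])
    gmaps = _global_maps(bundle, train_ids + val_ids, tiled, unet.depth)
    region = train_region_model([(gmaps[s], labels[s]) for s in train_ids],
                                [(gmaps[s], labels[s]) for s in val_ids],
                                unet, rtrain)
    from .evaluation import roc_auc
    indep_scores, region_scores, patch_labels = [], [], []
    for sid in val_ids:
        grid, patches = tiled[sid]
        if not patches:
            continue
        pixels = np.stack([p.pixels for p in patches])
        indep_scores.extend(predict_patch_probabilities(bundle.model, pixels,
                                                        bundle.crop_px))
        pmap = predict_probability_map(region.model, gmaps[sid])
        region_scores.extend(pmap.probs[p.grid_row, p.grid_col] for p in patches)
        patch_labels.extend(p.y for p in patches)
    return {"independent_auc": roc_auc(indep_scores, patch_labels),
            "region_auc": roc_auc(region_scores, patch_labels),
            "n_val_patches": len(patch_labels)}
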