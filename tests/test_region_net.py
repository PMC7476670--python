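"""Region-correlation stage: reassembly, mask-gated loss, training
contracts, probability-map prediction."""

import dataclasses

import numpy as np
import pytest

import histocorr.nn as nn
from histocorr.region_net import (GlobalFeatureMap, RegionTrainConfig,
                                  UNetConfig, assemble_global_features,
                                  cell_class_weights,
                                  masked_weighted_cross_entropy,
                                  predict_probability_map, train_region_model)
from histocorr.patch_net import ClassWeights
from histocorr.tiling import PatchGrid


def _grid(cells, shape, slide_id="s"):
    tumor = np.zeros(shape, np.uint8)
    index = {}
    for i, cell in enumerate(cells):
        tumor[cell] = 1
        index[cell] = i
    return PatchGrid(slide_id, shape, tumor, index)


def _random_items(rng, n_slides, shape=(6, 6), c=8, depth=2):
    items = []
    for i in range(n_slides):
        cells = [(r, q) for r in range(shape[0]) for q in range(shape[1])
                 if rng.random() < 0.5]
        if not cells:
            cells = [(0, 0)]
        grid = _grid(cells, shape, slide_id=f"s{i}")
        feats = {cell: rng.normal(size=c) for cell in cells}
        items.append((assemble_global_features(feats, grid, depth=depth),
                      "POS" if i % 2 else "NEG"))
    return items


class TestAssembly:
    def test_single_cell_placement(self):
        grid = _grid([(2, 3)], (5, 5))
        gmap = assemble_global_features({(2, 3): np.arange(4.0)}, grid, depth=2)
        top, _, left, _ = gmap.pad_info
        nz = np.argwhere(gmap.features.any(axis=2))
        assert nz.tolist() == [[top + 2, left + 3]]

    def test_padding_is_symmetric_lean_right(self):
        grid = _grid([(0, 0)], (5, 5))
        gmap = assemble_global_features({(0, 0): np.zeros(2)}, grid, depth=2)
        assert gmap.features.shape[:2] == (8, 8)
        assert gmap.pad_info == (1, 2, 1, 2)
        assert gmap.grid_shape == (5, 5)

    def test_roundtrip_reproduces_feature_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            shape = (int(rng.integers(3, 9)), int(rng.integers(3, 9)))
            cells = [(r, c) for r in range(shape[0]) for c in range(shape[1])
                     if rng.random() < 0.4] or [(0, 0)]
            grid = _grid(cells, shape)
            feats = {cell: rng.normal(size=5) for cell in cells}
            gmap = assemble_global_features(feats, grid, depth=2)
            top, _, left, _ = gmap.pad_info
            for cell in cells:
                assert np.array_equal(gmap.features[top + cell[0], left + cell[1]],
                                      feats[cell].astype(np.float32))
            # unoccupied and padded cells are zero
            occ = {(top + r, left + c) for r, c in cells}
            for r in range(gmap.features.shape[0]):
                for c in range(gmap.features.shape[1]):
                    if (r, c) not in occ:
                        assert not gmap.features[r, c].any()

    def test_missing_feature_lists_cells(self):
        grid = _grid([(0, 0), (1, 1)], (2, 2))
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            assemble_global_features({(0, 0): np.zeros(3)}, grid, depth=1)


class TestMaskedLoss:
    def test_single_cell_closed_form(self):
        loss = masked_weighted_cross_entropy(
            np.array([[0.5]]), 1, np.array([[1]]),
            ClassWeights(w_pos=1.0, w_neg=1.0))
        assert loss == pytest.approx(-np.log(0.5), abs=1e-6)

    def test_off_mask_perturbation_leaves_loss_identical(self):
        rng = np.random.default_rng(1)
        p = rng.random((4, 4))
        mask = np.zeros((4, 4)); mask[1:3, 1:3] = 1
        base = masked_weighted_cross_entropy(p, 0, mask)
        p2 = p.copy(); p2[mask == 0] = rng.random(12)
        assert masked_weighted_cross_entropy(p2, 0, mask) == base

    def test_perfect_prediction_limit(self):
        p = np.full((2, 2), 1 - 1e-9)
        assert masked_weighted_cross_entropy(p, 1, np.ones((2, 2))) < 1e-8

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert masked_weighted_cross_entropy(np.ones((2, 2)) * 0.5, 1,
                                                 np.zeros((2, 2))) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            masked_weighted_cross_entropy(np.ones((2, 2)), 1, np.ones((3, 3)))


class TestTraining:
    def test_constant_lr_history_and_determinism(self):
        rng = np.random.default_rng(2)
        train = _random_items(rng, 6, c=8)
        val = [(dataclasses.replace(g, slide_id="v" + g.slide_id), lab)
               for g, lab in _random_items(rng, 4, c=8)]
        unet = UNetConfig(in_channels=8, base_channels=4)
        cfg = RegionTrainConfig(epochs=3, seed=0)
        b1 = train_region_model(train, val, unet, cfg)
        assert b1.history["lr"].tolist() == [cfg.lr] * 3
        b2 = train_region_model(train, val, unet, cfg)
        assert b1.history["train_loss"].tolist() == b2.history["train_loss"].tolist()

    def test_refuses_slide_overlap(self):
        rng = np.random.default_rng(3)
        items = _random_items(rng, 4, c=4)
        unet = UNetConfig(in_channels=4, base_channels=4)
        with pytest.raises(ValueError, match="leak"):
            train_region_model(items, items[:2], unet,
                               RegionTrainConfig(epochs=1))

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        train = _random_items(rng, 2, c=8)
        val = [(dataclasses.replace(g, slide_id="v" + g.slide_id), lab)
               for g, lab in _random_items(rng, 2, c=8)]
        with pytest.raises(ValueError, match="channels"):
            train_region_model(train, val, UNetConfig(in_channels=5),
                               RegionTrainConfig(epochs=1))

    def test_cell_weights_balance_cell_counts(self):
        rng = np.random.default_rng(5)
        items = _random_items(rng, 6, c=4)
        w = cell_class_weights(items)
        n_pos = sum(int(g.tumor_cells.sum()) for g, lab in items if lab == "POS")
        n_neg = sum(int(g.tumor_cells.sum()) for g, lab in items if lab == "NEG")
        assert w.w_pos * n_pos == pytest.approx(w.w_neg * n_neg)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(6)
    model = nn.UNet(in_channels=8, base_channels=4, depth=2, seed=1)
    (gmap, _), = _random_items(rng, 1, shape=(5, 7), c=8)
    return model, gmap


class TestPrediction:
    def test_off_mask_cells_exactly_zero(self, setup):
        model, gmap = setup
        pmap = predict_probability_map(model, gmap)
        assert np.all(pmap.probs[pmap.tumor_cells == 0] == 0.0)
        assert np.all((pmap.probs >= 0) & (pmap.probs <= 1))

    def test_values_are_logistic_of_raw_outputs(self, setup):
        model, gmap = setup
        x = np.ascontiguousarray(
            gmap.features.transpose(2, 0, 1)[None]).astype(np.float32)
        raw = model.forward(x, train=False)[0]
        pmap = predict_probability_map(model, gmap)
        top, _, left, _ = gmap.pad_info
        for r, c in np.argwhere(pmap.tumor_cells):
            expect = 1 / (1 + np.exp(-raw[top + r, left + c]))
            assert pmap.probs[r, c] == pytest.approx(expect, abs=1e-6)

    def test_padding_removed_from_output(self, setup):
        model, gmap = setup
        pmap = predict_probability_map(model, gmap)
        assert pmap.probs.shape == (5, 7)

    def test_channel_mismatch_rejected(self, setup):
        model, gmap = setup
        bad = dataclasses.replace(gmap, features=gmap.features[..., :4])
        with pytest.raises(ValueError):
            predict_probability_map(model, bad)


def test_region_model_is_sensitive_to_spatial_arrangement():
    """Permuting occupied-cell features changes the region model's map,
    while the independent slide mean over the same posteriors does not."""
    rng = np.random.default_rng(7)
    model = nn.UNet(in_channels=8, base_channels=4, depth=2, seed=2)
    cells = [(r, c) for r in range(6) for c in range(6) if rng.random() < 0.6]
    grid = _grid(cells, (6, 6))
    feats = {cell: rng.normal(size=8) for cell in cells}
    gmap = assemble_global_features(feats, grid, depth=2)
    perm = rng.permutation(len(cells))
    pfeats = {cell: feats[cells[perm[i]]] for i, cell in enumerate(cells)}
    pmap1 = predict_probability_map(model, gmap)
    pmap2 = predict_probability_map(
        model, assemble_global_features(pfeats, grid, depth=2))
    assert not np.allclose(pmap1.probs, pmap2.probs)
    # the permutation-invariant baseline: mean over an unordered set
    from histocorr.evaluation import slide_probability
    vals = rng.random(len(cells))
    assert slide_probability(vals) == pytest.approx(
        slide_probability(vals[perm]))
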