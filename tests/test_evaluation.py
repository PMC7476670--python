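"""Aggregation, folds, ROC/AUC, bootstrap CIs, threshold metrics, rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histocorr.evaluation import (bootstrap_auc_ci, ensemble_average,
                                  evaluate_scores, make_slide_folds,
                                  render_probability_map, roc_auc, roc_points,
                                  slide_probability, threshold_metrics)
from histocorr.region_net import ProbabilityMap


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSlideProbability:
    def test_arithmetic_mean(self):
        assert slide_probability([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert slide_probability([0.7]) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            slide_probability([])

    def test_map_variant_equals_list_variant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = (rng.random((6, 6)) < 0.5).astype(np.uint8)
            if mask.sum() == 0:
                mask[0, 0] = 1
            probs = rng.random((6, 6)) * mask
            pmap = ProbabilityMap("s", probs, mask)
            assert slide_probability(pmap) == pytest.approx(
                slide_probability(probs[mask == 1]))

    def test_map_without_tumor_cells_rejected(self):
        with pytest.raises(ValueError):
            slide_probability(ProbabilityMap("s", np.zeros((2, 2)),
                                             np.zeros((2, 2), np.uint8)))


class TestFolds:
    @staticmethod
    def _manifest(n_pos, n_neg):
        return pd.DataFrame({
            "slide_id": [f"s{i}" for i in range(n_pos + n_neg)],
            "label": ["POS"] * n_pos + ["NEG"] * n_neg})

    def test_cohort_of_140_splits_into_balanced_folds(self):
        fs = make_slide_folds(self._manifest(66, 74), k=5, seed=0)
        man = self._manifest(66, 74).set_index("slide_id")
        for k in range(1, 6):
            fold = fs.fold_slides(k)
            assert len(fold) == 28
            assert sum(man.loc[s, "label"] == "POS" for s in fold) in (13, 14)

    def test_folds_partition_all_slides(self):
        fs = make_slide_folds(self._manifest(7, 9), k=3, seed=1)
        all_ids = set(self._manifest(7, 9)["slide_id"])
        seen = [s for k in range(1, 4) for s in fs.fold_slides(k)]
        assert sorted(seen) == sorted(all_ids)
        for k in range(1, 4):
            assert not set(fs.train_slides(k)) & set(fs.val_slides(k))

    def test_deterministic_for_fixed_seed(self):
        a = make_slide_folds(self._manifest(10, 12), k=4, seed=7)
        b = make_slide_folds(self._manifest(10, 12), k=4, seed=7)
        assert a.assignment == b.assignment

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_slide_folds(self._manifest(6, 0), k=2, seed=0)

    def test_small_class_warns(self):
        with pytest.warns(UserWarning):
            make_slide_folds(self._manifest(2, 10), k=4, seed=0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n_pos=st.integers(5, 40), n_neg=st.integers(5, 40),
           seed=st.integers(0, 100))
    def test_size_invariants_hold_generally(self, n_pos, n_neg, seed):
        fs = make_slide_folds(self._manifest(n_pos, n_neg), k=5, seed=seed)
        man = self._manifest(n_pos, n_neg).set_index("slide_id")
        sizes, pos = [], []
        for k in range(1, 6):
            fold = fs.fold_slides(k)
            sizes.append(len(fold))
            pos.append(sum(man.loc[s, "label"] == "POS" for s in fold))
        assert max(sizes) - min(sizes) <= 1
        assert max(pos) - min(pos) <= 1


class TestEnsemble:
    def test_identical_models_are_a_noop(self):
        lists = [[0.1, 0.5, 0.9]] * 5
        assert np.allclose(ensemble_average(lists), lists[0])

    def test_two_model_average_and_order_invariance(self):
        assert ensemble_average([[0.2], [0.8]])[0] == pytest.approx(0.5)
        a = ensemble_average([[0.1, 0.9], [0.5, 0.3], [0.2, 0.2]])
        b = ensemble_average([[0.2, 0.2], [0.1, 0.9], [0.5, 0.3]])
        assert np.allclose(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([[0.1, 0.2], [0.3]])


class TestAUC:
    def test_canonical_values(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.9], size=30)  # with ties
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])),
                    min_size=2, max_size=12))
    def test_equals_pairwise_concordance(self, pairs):
        y = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        if min(y) == max(y):
            return
        assert roc_auc(s, y) == pytest.approx(brute_force_auc(s, y))


def test_roc_curve_hits_both_endpoints():
    rng = np.random.default_rng(2)
    s = rng.random(40)
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    df = roc_points(s, y)
    pts = set(zip((1 - df.specificity).round(9), df.sensitivity.round(9)))
    assert (0.0, 0.0) in pts and (1.0, 1.0) in pts
    assert (df.threshold.diff().dropna() <= 0).all()


class TestBootstrap:
    def test_interval_contains_point_auc(self):
        rng = np.random.default_rng(3)
        for seed in range(20):
            s = np.concatenate([rng.normal(1, 1, 25), rng.normal(0, 1, 25)])
            y = np.array([1] * 25 + [0] * 25)
            lo, hi = bootstrap_auc_ci(s, y, n_boot=400, seed=seed)
            assert lo <= roc_auc(s, y) <= hi

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (100, 1000):
            ws = []
            for seed in range(10):
                rng = np.random.default_rng(100 + seed)
                s = np.concatenate([rng.normal(1, 1, n // 2),
                                    rng.normal(0, 1, n // 2)])
                y = np.array([1] * (n // 2) + [0] * (n // 2))
                lo, hi = bootstrap_auc_ci(s, y, n_boot=300, seed=seed)
                ws.append(hi - lo)
            widths[n] = np.median(ws)
        assert widths[1000] < widths[100]

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc_ci([0.1, 0.9], [0, 1], n_boot=10)


class TestThresholdMetrics:
    def test_hand_confusion_matrix(self):
        m = threshold_metrics([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert m["tp"] == m["fn"] == m["fp"] == m["tn"] == 1
        for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert m[key] == pytest.approx(0.5)

    def test_perfect_separation(self):
        m = threshold_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert m[key] == 1.0

    def test_score_at_threshold_called_negative(self):
        m = threshold_metrics([0.5, 0.9], [1, 0], threshold=0.5)
        assert m["fn"] == 1   # the 0.5-scoring positive is predicted negative


def test_evaluate_scores_report_invariants():
    rng = np.random.default_rng(4)
    s = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
    y = np.array([1] * 30 + [0] * 30)
    rep = evaluate_scores(s, y, n_boot=300, seed=0)
    assert rep.ci[0] <= rep.auc <= rep.ci[1]
    assert rep.n_pos == rep.n_neg == 30
    if rep.precision + rep.sensitivity > 0:
        assert rep.f1 == pytest.approx(
            2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity))
    row = rep.as_row("slide", "ensemble")
    assert row["level"] == "slide" and 0 <= row["auc"] <= 1


class TestRenderMap:
    def _map(self, value):
        probs = np.full((3, 3), value, float)
        mask = np.zeros((3, 3), np.uint8)
        mask[1, 1] = 1
        return ProbabilityMap("s", probs * mask, mask)

    def test_extremes_map_to_grey_and_blue(self):
        grey = render_probability_map(self._map(0.0), cell_px=2)
        blue = render_probability_map(self._map(1.0), cell_px=2)
        assert tuple(grey[2, 2]) == (158, 158, 158)
        assert tuple(blue[2, 2]) == (40, 80, 220)

    def test_off_mask_is_background_regardless_of_values(self):
        pmap = self._map(0.7)
        img = render_probability_map(pmap, cell_px=2)
        assert tuple(img[0, 0]) == (255, 255, 255)

    def test_file_written(self, tmp_path):
        out = tmp_path / "map.png"
        render_probability_map(self._map(0.3), out_path=out)
        assert out.exists() and out.stat().st_size > 0
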