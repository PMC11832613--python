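"""Threshold calibration, the binarization rule, and the reference classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ichscreen.classifier import (
    SUBTYPES,
    HeuristicSliceClassifier,
    LabeledScoreSet,
    SliceContext,
    SmallTrainedClassifier,
    SubtypeProbabilities,
    ThresholdSet,
    binarize,
    calibrate_threshold,
    fit_small_model,
)
from ichscreen.errors import CalibrationError, GeometryError
from ichscreen.windowing import DEFAULT_WINDOWS, compose_tri_window


def youden_brute_force(scores, labels):
    """Independent exhaustive oracle over all achievable strict-> cuts."""
    best = (-1.0, None)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for theta in sorted({0.0, *scores}):
        sen = sum(1 for s, y in zip(scores, labels) if y == 1 and s > theta) / n_pos
        spec = sum(1 for s, y in zip(scores, labels) if y == 0 and s <= theta) / n_neg
        j = sen + spec
        if j > best[0] + 1e-12:
            best = (j, theta)
    return best


class TestCalibrateThreshold:
    def test_separated_scores_return_smallest_achieving_cut(self):
        data = LabeledScoreSet(scores=[0.1, 0.2, 0.8, 0.9], labels=[0, 0, 1, 1])
        theta = calibrate_threshold(data)
        assert theta == pytest.approx(0.2)

    def test_anti_informative_pair_matches_brute_force(self):
        scores, labels = [0.4, 0.6], [1, 0]
        j, theta = youden_brute_force(scores, labels)
        got = calibrate_threshold(LabeledScoreSet(scores=scores, labels=labels))
        assert got == pytest.approx(theta)

    def test_perfectly_separable_reaches_sum_two(self, rng):
        scores = np.concatenate([rng.uniform(0, 0.4, 50), rng.uniform(0.6, 1.0, 50)])
        labels = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        theta = calibrate_threshold(LabeledScoreSet(scores=scores, labels=labels))
        sen = np.mean(scores[labels == 1] > theta)
        spec = np.mean(scores[labels == 0] <= theta)
        assert sen + spec == pytest.approx(2.0)

    def test_single_class_labels_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold(LabeledScoreSet(scores=[0.1, 0.9], labels=[1, 1]))

    @settings(deadline=None, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 60))
    def test_oracle_equivalence_on_random_sets(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(0, 1, n), 2)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        j, theta = youden_brute_force(list(scores), list(labels))
        got = calibrate_threshold(LabeledScoreSet(scores=scores, labels=labels))
        assert got == pytest.approx(theta)


def make_probs(**kw):
    base = dict(slice_index=0, p_iph=0, p_ivh=0, p_sah=0, p_sdh=0, p_edh=0, p_any=0)
    base.update(kw)
    return SubtypeProbabilities(**base)


class TestBinarize:
    def test_any_gate_blocks_subtype_detection(self):
        probs = make_probs(p_iph=0.9, p_any=0.3)
        det = binarize(probs, ThresholdSet())
        assert det["IPH"] is False

    def test_both_above_thresholds_detects(self):
        probs = make_probs(p_iph=0.9, p_any=0.9)
        assert binarize(probs, ThresholdSet())["IPH"] is True

    def test_equality_is_not_above(self):
        probs = make_probs(p_iph=0.5, p_any=0.9)
        assert binarize(probs, ThresholdSet())["IPH"] is False

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_monotone_raising_probabilities_never_unsets_flags(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 6)
        thresholds = ThresholdSet(*rng.uniform(0, 1, 6))
        lo = make_probs(
            p_iph=p[0], p_ivh=p[1], p_sah=p[2], p_sdh=p[3], p_edh=p[4], p_any=p[5]
        )
        bump = np.minimum(p + rng.uniform(0, 0.3, 6), 1.0)
        hi = make_probs(
            p_iph=bump[0], p_ivh=bump[1], p_sah=bump[2],
            p_sdh=bump[3], p_edh=bump[4], p_any=bump[5],
        )
        det_lo, det_hi = binarize(lo, thresholds), binarize(hi, thresholds)
        for s in SUBTYPES:
            assert det_hi[s] or not det_lo[s]


def synthetic_slice(side=64, lesion_radius_px=0, lesion_hu=70.0):
    """A minimal head-like slice: parenchyma disc, optional central lesion."""
    hu = np.full((side, side), -1000.0)
    yy, xx = np.mgrid[0:side, 0:side]
    d = np.hypot(yy - side / 2, xx - side / 2)
    hu[d <= side * 0.4] = 35.0
    if lesion_radius_px > 0:
        hu[d <= lesion_radius_px] = lesion_hu
    return hu, d <= side * 0.4


class TestHeuristicClassifier:
    def context(self, mask):
        return SliceContext(tiv_mask=mask, pixel_spacing=(0.9, 0.9))

    def test_zero_evidence_gives_baseline(self):
        clf = HeuristicSliceClassifier()
        hu, mask = synthetic_slice()
        img = compose_tri_window(hu, DEFAULT_WINDOWS)
        probs = clf.classify(img, self.context(mask))
        baseline = 1 / (1 + np.exp(clf.logistic_midpoint / clf.logistic_scale))
        assert probs.p_any == pytest.approx(baseline)
        assert probs.p_any < 0.5  # below any shipped threshold

    def test_lesion_raises_p_any_and_p_iph_above_baseline(self):
        clf = HeuristicSliceClassifier()
        hu0, mask = synthetic_slice()
        hu1, _ = synthetic_slice(lesion_radius_px=6)
        ctx = self.context(mask)
        p0 = clf.classify(compose_tri_window(hu0, DEFAULT_WINDOWS), ctx)
        p1 = clf.classify(compose_tri_window(hu1, DEFAULT_WINDOWS), ctx)
        assert p1.p_any > p0.p_any
        assert p1.p_iph > p0.p_iph

    def test_deterministic(self):
        clf = HeuristicSliceClassifier()
        hu, mask = synthetic_slice(lesion_radius_px=5)
        img = compose_tri_window(hu, DEFAULT_WINDOWS)
        a = clf.classify(img, self.context(mask))
        b = clf.classify(img, self.context(mask))
        assert a == b

    def test_nested_lesions_give_nondecreasing_p_any(self):
        clf = HeuristicSliceClassifier()
        _, mask = synthetic_slice()
        ctx = self.context(mask)
        last = -1.0
        for r in (0, 3, 5, 8, 12):
            hu, _ = synthetic_slice(lesion_radius_px=r)
            p = clf.classify(compose_tri_window(hu, DEFAULT_WINDOWS), ctx).p_any
            assert p >= last
            last = p

    def test_shape_mismatch_raises(self):
        clf = HeuristicSliceClassifier()
        hu, mask = synthetic_slice()
        img = compose_tri_window(hu, DEFAULT_WINDOWS)
        with pytest.raises(GeometryError):
            clf.classify(img, self.context(mask[:32, :32]))


class TestSmallModel:
    def build_training_set(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        items = []
        for k in range(n):
            lesion = k % 2 == 1
            hu, _ = synthetic_slice(lesion_radius_px=rng.integers(4, 9) if lesion else 0)
            hu += rng.normal(0, 3, hu.shape)
            img = compose_tri_window(hu, DEFAULT_WINDOWS, slice_index=k)
            labels = {"Any": int(lesion), "IPH": int(lesion)}
            items.append((img, labels))
        return items

    def test_informative_fit_beats_chance(self):
        from sklearn.metrics import roc_auc_score

        items = self.build_training_set(n=120, seed=1)
        model = fit_small_model(items[:80], seed=0)
        ctx = SliceContext(tiv_mask=np.ones((64, 64), bool), pixel_spacing=(0.9, 0.9))
        scores = [model.classify(img, ctx).p_any for img, _ in items[80:]]
        truth = [labels["Any"] for _, labels in items[80:]]
        assert roc_auc_score(truth, scores) > 0.5

    def test_fixed_seed_reproduces_serialization(self):
        items = self.build_training_set(n=40, seed=2)
        blob1 = fit_small_model(items, seed=7).to_bytes()
        blob2 = fit_small_model(items, seed=7).to_bytes()
        assert blob1 == blob2
        assert isinstance(SmallTrainedClassifier.from_bytes(blob1), SmallTrainedClassifier)

    def test_empty_training_set_raises(self):
        with pytest.raises(CalibrationError):
            fit_small_model([], seed=0)

    def test_single_class_any_raises(self):
        items = [
            (compose_tri_window(synthetic_slice()[0], DEFAULT_WINDOWS), {"Any": 0})
            for _ in range(10)
        ]
        with pytest.raises(CalibrationError):
            fit_small_model(items, seed=0)
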