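"""Synthetic scene/annotator/predictor/experiment generators."""

import numpy as np
import pytest

from consenseg.io import connected_components, filter_min_size
from consenseg.metrics import evaluate_masks
from consenseg.simulate import (
    AnnotatorProfile,
    SceneConfig,
    generate_experiment,
    generate_scene,
    simulate_annotator,
    simulate_predictor,
)
from consenseg.stats import mann_whitney


class TestGenerateScene:
    def test_empty_scene(self):
        img, truth, region = generate_scene(SceneConfig(n_objects=0, seed=1))
        assert truth.n_objects == 0
        assert img.pixels.shape == (256, 256)
        assert region.mask.all()

    def test_object_count_contract(self):
        _, truth, _ = generate_scene(SceneConfig(seed=2))
        assert truth.n_objects == 35

    def test_bit_identical_under_seed(self):
        a = generate_scene(SceneConfig(seed=3))
        b = generate_scene(SceneConfig(seed=3))
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_overcrowded_request_fails_with_hint(self):
        with pytest.raises(RuntimeError, match="reduce"):
            generate_scene(SceneConfig(shape=(48, 48), n_objects=60, seed=1))

    def test_intensities_within_bit_depth(self):
        img, _, _ = generate_scene(SceneConfig(seed=4, bit_depth=8))
        assert img.pixels.max() <= 255


class TestSimulateAnnotator:
    def test_noise_free_profile_reproduces_truth(self):
        img, truth, _ = generate_scene(SceneConfig(shape=(96, 96), n_objects=6, seed=5))
        prof = AnnotatorProfile(boundary_jitter=0.0, fp_rate=0.0, dilation_bias=0.0,
                               miss_curve=lambda i: 0.0, seed=1)
        ann = simulate_annotator(truth, img, prof)
        np.testing.assert_array_equal(ann.binary(), truth.binary())

    def test_certain_miss_leaves_only_false_positives(self):
        img, truth, _ = generate_scene(SceneConfig(shape=(96, 96), n_objects=6, seed=6))
        prof = AnnotatorProfile(miss_curve=lambda i: 1.0, fp_rate=3.0, seed=2)
        ann = simulate_annotator(truth, img, prof)
        assert not (ann.binary() & truth.binary()).any()

    def test_detection_frequency_tracks_miss_curve(self):
        # aggregate realized detection per intensity bin vs the logistic curve
        prof_proto = AnnotatorProfile(midpoint=30.0, width=12.0, boundary_jitter=0.0,
                                      fp_rate=0.0)
        recorded = []  # (mean intensity above background, detected)
        for s in range(200):
            img, truth, _ = generate_scene(
                SceneConfig(shape=(96, 96), n_objects=6, seed=700 + s)
            )
            prof = AnnotatorProfile(midpoint=30.0, width=12.0, boundary_jitter=0.0,
                                    fp_rate=0.0, seed=900 + s)
            ann = simulate_annotator(truth, img, prof)
            pix = img.pixels.astype(float)
            for k in truth.ids:
                obj = truth.labels == k
                inten = pix[obj].mean() - 20.0
                detected = (ann.binary() & obj).sum() > 0.5 * obj.sum()
                recorded.append((inten, detected))
        arr = np.array(recorded)
        bins = np.quantile(arr[:, 0], [0, 0.25, 0.5, 0.75, 1.0])
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
            n = sel.sum()
            expect = np.mean(
                [prof_proto.detection_probability(v) for v in arr[sel, 0]]
            )
            sigma = np.sqrt(max(expect * (1 - expect) / n, 1e-9))
            assert abs(arr[sel, 1].mean() - expect) <= 3 * sigma + 1e-9

    def test_annotated_objects_stay_connected(self):
        img, truth, _ = generate_scene(SceneConfig(shape=(96, 96), n_objects=8, seed=7))
        prof = AnnotatorProfile(boundary_jitter=2.5, fp_rate=0.0, seed=3)
        ann = simulate_annotator(truth, img, prof)
        for k in ann.ids:
            assert connected_components(ann.labels == k).n_objects == 1


class TestSimulatePredictor:
    def test_perfect_quality_reproduces_truth(self):
        _, truth, _ = generate_scene(SceneConfig(shape=(96, 96), n_objects=6, seed=8))
        m = simulate_predictor(truth, 1.0, seed=1)
        np.testing.assert_array_equal(m > 0.5, truth.binary())

    def test_zero_quality_is_noise_floor(self):
        f1s = []
        for s in range(20):
            _, truth, _ = generate_scene(SceneConfig(shape=(96, 96), n_objects=6,
                                                     seed=20 + s))
            m = simulate_predictor(truth, 0.0, seed=50 + s)
            pred = filter_min_size(connected_components(m > 0.5), 9)
            _, det = evaluate_masks(pred, truth)
            f1s.append(det.f1)
        assert np.mean(f1s) < 0.2

    def test_f1_increases_with_quality(self):
        scores = {}
        for q in (0.2, 0.5, 0.8, 1.0):
            f1s = []
            for s in range(10):
                _, truth, _ = generate_scene(
                    SceneConfig(shape=(96, 96), n_objects=6, seed=40 + s)
                )
                m = simulate_predictor(truth, q, seed=60 + s)
                pred = filter_min_size(connected_components(m > 0.5), 9)
                _, det = evaluate_masks(pred, truth)
                f1s.append(det.f1)
            scores[q] = np.mean(f1s)
        vals = [scores[q] for q in (0.2, 0.5, 0.8, 1.0)]
        assert vals == sorted(vals)

    def test_averaging_four_predictors_usually_beats_mean_member(self):
        rng = np.random.default_rng(9)
        better = 0
        n = 100
        for s in range(n):
            _, truth, _ = generate_scene(
                SceneConfig(shape=(96, 96), n_objects=6, seed=3000 + s)
            )
            maps = [simulate_predictor(truth, 0.7, seed=int(rng.integers(2**31)))
                    for _ in range(4)]
            f1s = []
            for m in maps:
                pred = filter_min_size(connected_components(m > 0.5), 9)
                f1s.append(evaluate_masks(pred, truth)[1].f1)
            avg = filter_min_size(connected_components(np.mean(maps, axis=0) > 0.5), 9)
            ens_f1 = evaluate_masks(avg, truth)[1].f1
            better += ens_f1 >= np.mean(f1s)
        assert better >= 60


class TestGenerateExperiment:
    BASE = SceneConfig(shape=(128, 128), n_objects=10)

    def test_table_row_count(self):
        exp = generate_experiment([("a", 3, 1.0), ("b", 2, 1.5)], self.BASE, seed=1)
        assert len(exp.table) == 5
        assert len(exp.images) == 5

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            generate_experiment([("a", 1, 0.0)], self.BASE, seed=1)

    def test_null_effect_false_positive_rate_is_nominal(self):
        sig = 0
        for s in range(50):
            exp = generate_experiment([("a", 8, 1.0), ("b", 8, 1.0)], self.BASE, seed=s)
            counts = {
                g: [t.n_objects for t, r in zip(exp.truths, exp.table.itertuples())
                    if r.group == g]
                for g in ("a", "b")
            }
            _, p = mann_whitney(counts["a"], counts["b"])
            sig += p <= 0.05
        assert sig <= 10  # ~5% nominal rate, generous bound

    def test_density_shift_detected_with_high_power(self):
        sig = 0
        for s in range(50):
            exp = generate_experiment(
                [("a", 30, 1.0), ("b", 30, 1.5)], self.BASE, seed=1000 + s
            )
            counts = {
                g: [t.n_objects for t, r in zip(exp.truths, exp.table.itertuples())
                    if r.group == g]
                for g in ("a", "b")
            }
            _, p = mann_whitney(counts["a"], counts["b"])
            sig += p <= 0.05
        assert sig >= 45  # >= 90% of seeds
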