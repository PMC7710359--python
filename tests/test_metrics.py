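"""Object-level IoU, Hungarian matching, detection scores, Fleiss' kappa."""

import itertools

import numpy as np
import pytest

from consenseg.io import LabelMask
from consenseg.metrics import (
    AgreementTable,
    build_agreement_table,
    detection_scores,
    fleiss_kappa,
    match_objects,
    mean_iou,
    pairwise_iou,
)
from conftest import random_blob_mask


def brute_force_total_iou(iou: np.ndarray) -> float:
    """Exhaustive optimum of the assignment problem (pad to square)."""
    a, b = iou.shape
    n = max(a, b)
    padded = np.zeros((n, n))
    padded[:a, :b] = iou
    return max(
        sum(padded[i, p] for i, p in enumerate(perm))
        for perm in itertools.permutations(range(n))
    )


def square_mask(r0, c0, side, shape=(32, 32), label=1, base=None):
    arr = np.zeros(shape, dtype=np.int32) if base is None else base
    arr[r0 : r0 + side, c0 : c0 + side] = label
    return arr


class TestPairwiseIoU:
    def test_identical_object(self):
        m = LabelMask(square_mask(5, 5, 4))
        assert pairwise_iou(m, m)[0, 0] == 1.0

    def test_disjoint_objects(self):
        a = LabelMask(square_mask(0, 0, 4))
        b = LabelMask(square_mask(20, 20, 4))
        assert pairwise_iou(a, b)[0, 0] == 0.0

    def test_shifted_square(self):
        a = LabelMask(square_mask(5, 5, 3))
        b = LabelMask(square_mask(5, 6, 3))
        assert pairwise_iou(a, b)[0, 0] == pytest.approx(6 / 12)

    def test_symmetry_and_range(self, rng):
        a = random_blob_mask(rng)
        b = random_blob_mask(rng)
        ab = pairwise_iou(a, b)
        np.testing.assert_allclose(ab, pairwise_iou(b, a).T)
        assert ab.min() >= 0 and ab.max() <= 1


class TestMatching:
    def test_diagonal_preferred_when_total_higher(self):
        m = match_objects(np.array([[0.6, 0.3], [0.4, 0.5]]))
        assert {(p[0], p[1]) for p in m.pairs} == {(1, 1), (2, 2)}
        assert m.total_iou == pytest.approx(1.1)

    def test_cross_assignment(self):
        m = match_objects(np.array([[0.0, 0.7], [0.6, 0.0]]))
        assert {(p[0], p[1]) for p in m.pairs} == {(1, 2), (2, 1)}

    def test_single_overlapping_pair(self):
        m = match_objects(np.array([[0.4]]))
        assert len(m.pairs) == 1

    def test_zero_iou_pairs_never_emitted(self):
        m = match_objects(np.array([[0.0, 0.0], [0.0, 0.9]]))
        assert len(m.pairs) == 1
        assert m.unmatched_source == [1] and m.unmatched_target == [1]

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            a, b = rng.integers(1, 7, size=2)
            iou = rng.random((a, b)) * (rng.random((a, b)) < 0.7)
            assert match_objects(iou).total_iou == pytest.approx(
                brute_force_total_iou(iou)
            )


class TestMeanIoUAndDetection:
    def test_identical_masks_perfect(self, rng):
        m = random_blob_mask(rng)
        match = match_objects(pairwise_iou(m, m))
        assert mean_iou(match) == 1.0
        assert detection_scores(match).f1 == 1.0

    def test_mean_of_pairs(self):
        from consenseg.metrics import Matching

        match = Matching(pairs=[(1, 1, 0.5), (2, 2, 0.7)], unmatched_source=[],
                         unmatched_target=[])
        assert mean_iou(match) == pytest.approx(0.6)

    def test_disjoint_masks_mean_iou_undefined(self):
        a = LabelMask(square_mask(0, 0, 4))
        b = LabelMask(square_mask(20, 20, 4))
        assert np.isnan(mean_iou(match_objects(pairwise_iou(a, b))))

    def test_pair_exactly_at_threshold_counts_fn_fp(self):
        # IoU exactly 0.5 at t=0.5 is *not* a true positive
        a = LabelMask(square_mask(5, 5, 3))
        b = LabelMask(square_mask(5, 6, 3))
        det = detection_scores(match_objects(pairwise_iou(a, b)), t=0.5)
        assert (det.tp, det.fn, det.fp) == (0, 1, 1)

    def test_two_vs_three_objects(self):
        arr_a = square_mask(2, 2, 4)
        arr_a = square_mask(20, 20, 4, base=arr_a, label=2)
        arr_b = square_mask(2, 2, 4)  # overlaps a:1 perfectly (IoU 1 > t)
        arr_b = square_mask(10, 10, 4, base=arr_b, label=2)
        arr_b = square_mask(26, 2, 4, base=arr_b, label=3)
        det = detection_scores(
            match_objects(pairwise_iou(LabelMask(arr_a), LabelMask(arr_b))), t=0.5
        )
        assert (det.tp, det.fn, det.fp) == (1, 1, 2)
        assert det.precision == pytest.approx(1 / 3)
        assert det.recall == pytest.approx(1 / 2)
        assert det.f1 == pytest.approx(0.4)

    def test_empty_conventions(self):
        empty = LabelMask(np.zeros((8, 8), dtype=np.int32))
        full = LabelMask(square_mask(1, 1, 3, shape=(8, 8)))
        det = detection_scores(match_objects(pairwise_iou(empty, empty)))
        assert det.f1 == 1.0
        det = detection_scores(match_objects(pairwise_iou(full, empty)))
        assert det.f1 == 0.0

    def test_precision_recall_monotone_in_t(self, rng):
        a = random_blob_mask(rng, n_blobs=8)
        b = random_blob_mask(rng, n_blobs=8)
        match = match_objects(pairwise_iou(a, b))
        prev_p, prev_r = 1.0, 1.0
        for t in (0.1, 0.3, 0.5, 0.7, 0.9):
            det = detection_scores(match, t=t)
            assert det.precision <= prev_p + 1e-12
            assert det.recall <= prev_r + 1e-12
            assert 0 <= det.f1 <= 1
            prev_p, prev_r = det.precision, det.recall


class TestAgreementTable:
    def test_perfect_agreement_with_auto_proposals(self, rng):
        m = random_blob_mask(rng, n_blobs=4)
        table = build_agreement_table([m, m, m], seed=0)
        obj = table.counts[~table.proposal_flags]
        prop = table.counts[table.proposal_flags]
        assert len(obj) == 4 and (obj[:, 1] == 3).all()
        assert len(prop) == 4 and (prop[:, 0] == 3).all()

    def test_constructed_two_rater_fixture(self):
        arr1 = square_mask(2, 2, 4)
        arr1 = square_mask(20, 20, 4, base=arr1, label=2)  # B: rater 1 only
        arr2 = square_mask(2, 2, 4)  # A: both raters
        t = build_agreement_table(
            [LabelMask(arr1), LabelMask(arr2)], n_proposals=2, seed=1
        )
        assert sorted(t.counts[:, 1].tolist()) == [0, 0, 1, 2]

    def test_deterministic_under_seed(self, rng):
        m1 = random_blob_mask(rng, n_blobs=5)
        m2 = random_blob_mask(rng, n_blobs=5)
        t1 = build_agreement_table([m1, m2], seed=42)
        t2 = build_agreement_table([m1, m2], seed=42)
        np.testing.assert_array_equal(t1.counts, t2.counts)


class TestFleissKappa:
    def test_unanimous_rows_give_one(self):
        table = AgreementTable(counts=np.array([[0, 3], [3, 0], [0, 3]]), d=3)
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_worked_two_rater_example(self):
        # rows n_i1 = {2,1,0,0}: Pbar=0.75, Pe=34/64 -> kappa = 0.21875/0.46875
        table = AgreementTable(counts=np.array([[0, 2], [1, 1], [2, 0], [2, 0]]), d=2)
        assert fleiss_kappa(table) == pytest.approx(0.21875 / 0.46875)

    def test_independent_coin_votes_near_zero(self):
        rng = np.random.default_rng(8)
        d = 5
        k = rng.binomial(d, 0.5, size=10_000)
        table = AgreementTable(counts=np.column_stack([d - k, k]), d=d)
        assert abs(fleiss_kappa(table)) < 0.05

    def test_single_class_table_undefined(self):
        table = AgreementTable(counts=np.array([[2, 0], [2, 0]]), d=2)
        assert fleiss_kappa(table) == 1.0  # unanimous -> perfect
        mixed = AgreementTable(counts=np.array([[1, 1], [1, 1]]), d=2)
        # observed agreement 0, chance from p_j = (.5,.5): kappa defined, negative
        assert fleiss_kappa(mixed) < 0

    def test_kappa_never_exceeds_one(self, rng):
        for _ in range(20):
            d = int(rng.integers(2, 6))
            k = rng.integers(0, d + 1, size=50)
            table = AgreementTable(counts=np.column_stack([d - k, k]), d=d)
            kap = fleiss_kappa(table)
            if not np.isnan(kap):
                assert kap <= 1.0 + 1e-12
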