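"""Object-level similarity and multi-rater agreement.

Segmentation masks are compared at the level of objects (ROIs): pairwise
intersection-over-union between all object pairs, an optimal one-to-one
assignment by the Hungarian method (maximizing total IoU), the Mean IoU
over matched pairs, detection precision/recall/F1 at an IoU threshold t,
and Fleiss' kappa over an IoU-matched object universe augmented with
random background proposals.

Conventions (fixed throughout): a true positive requires IoU strictly
greater than t (a pair at exactly t counts as FN + FP); the default
threshold is t = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import LabelMask

__all__ = [
    "Matching",
    "DetectionScores",
    "AgreementTable",
    "pairwise_iou",
    "match_objects",
    "mean_iou",
    "detection_scores",
    "evaluate_masks",
    "build_agreement_table",
    "fleiss_kappa",
]


@dataclass
class Matching:
    """Optimal source-target object assignment.

    ``pairs`` holds (source id, target id, IoU) triples with IoU > 0; ids
    are the 1-based object labels.  Unmatched ids are listed separately so
    the full object universes of both masks are recoverable.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_source: list[int]
    unmatched_target: list[int]

    @property
    def n_source(self) -> int:
        return len(self.pairs) + len(self.unmatched_source)

    @property
    def n_target(self) -> int:
        return len(self.pairs) + len(self.unmatched_target)

    @property
    def total_iou(self) -> float:
        return float(sum(p[2] for p in self.pairs))


@dataclass
class DetectionScores:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    t: float


@dataclass
class AgreementTable:
    """Fleiss table: row i counts raters voting object i background/foreground."""

    counts: np.ndarray  # (N, 2) int array, columns (n_i0, n_i1)
    d: int
    proposal_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be (N, 2): binary segmentation")
        if (self.counts.sum(axis=1) != self.d).any():
            raise ValueError("every row must sum to the rater count d")
        if len(self.proposal_flags) != len(self.counts):
            self.proposal_flags = np.zeros(len(self.counts), dtype=bool)


def pairwise_iou(source: LabelMask, target: LabelMask) -> np.ndarray:
    """(A, B) matrix of IoUs between every source and target object.

    Entry (a-1, b-1) = |a n b| / |a u b|; zero for disjoint objects.
    """
    if source.shape != target.shape:
        raise ValueError("masks must share a shape")
    A, B = source.n_objects, target.n_objects
    if A == 0 or B == 0:
        return np.zeros((A, B))
    s = source.labels.ravel().astype(np.int64)
    t = target.labels.ravel().astype(np.int64)
    inter = np.bincount(s * (B + 1) + t, minlength=(A + 1) * (B + 1)).reshape(A + 1, B + 1)
    area_s = inter.sum(axis=1)[1:, None]
    area_t = inter.sum(axis=0)[None, 1:]
    inter = inter[1:, 1:]
    union = area_s + area_t - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_objects(iou: np.ndarray) -> Matching:
    """Hungarian assignment maximizing total IoU; zero-IoU pairs are dropped."""
    iou = np.asarray(iou, dtype=float)
    if iou.size and iou.min() < 0:
        raise ValueError("IoU matrix must be non-negative")
    A, B = iou.shape
    pairs: list[tuple[int, int, float]] = []
    if A and B:
        rows, cols = linear_sum_assignment(-iou)
        for r, c in zip(rows, cols):
            if iou[r, c] > 0:
                pairs.append((int(r) + 1, int(c) + 1, float(iou[r, c])))
    used_s = {p[0] for p in pairs}
    used_t = {p[1] for p in pairs}
    return Matching(
        pairs=pairs,
        unmatched_source=[i for i in range(1, A + 1) if i not in used_s],
        unmatched_target=[i for i in range(1, B + 1) if i not in used_t],
    )


def mean_iou(matching: Matching) -> float:
    """Arithmetic mean IoU over matched pairs; NaN when nothing overlaps.

    By construction this measures segmentation similarity of matching
    objects only and neglects objects that do not overlap at all.
    """
    if not matching.pairs:
        return float("nan")
    return float(np.mean([p[2] for p in matching.pairs]))


def detection_scores(matching: Matching, t: float = 0.5) -> DetectionScores:
    """Detection similarity at IoU threshold t (TP requires IoU > t, strictly)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    tp = sum(1 for p in matching.pairs if p[2] > t)
    fn = matching.n_source - tp
    fp = matching.n_target - tp
    if tp + fp == 0 and tp + fn == 0:
        precision = recall = f1 = 1.0  # empty vs empty: perfect by convention
    else:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionScores(tp, fp, fn, precision, recall, f1, t)


def evaluate_masks(
    source: LabelMask, target: LabelMask, t: float = 0.5
) -> tuple[float, DetectionScores]:
    """One-call comparison: (Mean IoU, DetectionScores) of source vs target."""
    m = match_objects(pairwise_iou(source, target))
    return mean_iou(m), detection_scores(m, t=t)


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_agreement_table(
    masks: list[LabelMask],
    t: float = 0.5,
    n_proposals: int | str = "auto",
    seed: int | None = None,
) -> AgreementTable:
    """Build the Fleiss table over a unique-object universe plus proposals.

    The universe is formed by Hungarian matching between every rater pair at
    IoU > t, with matches merged transitively (union-find).  Row i counts the
    raters contributing an ROI to cluster i.  Background proposals — squares
    of median object area, rejection-sampled disjoint from every rater ROI —
    are appended as unanimous-background rows ("auto": one per unique object),
    so chance agreement is estimated over absent as well as present objects.
    """
    d = len(masks)
    if d < 2:
        raise ValueError("need at least two raters")
    if len({m.shape for m in masks}) != 1:
        raise ValueError("masks must share a shape")

    # node index per (rater, object id)
    offsets = np.cumsum([0] + [m.n_objects for m in masks])
    n_nodes = int(offsets[-1])
    dsu = _DSU(n_nodes)
    edges: list[tuple[int, int, float]] = []
    for r1 in range(d):
        for r2 in range(r1 + 1, d):
            iou = pairwise_iou(masks[r1], masks[r2])
            for sid, tid, v in match_objects(iou).pairs:
                if v > t:
                    a = offsets[r1] + sid - 1
                    b = offsets[r2] + tid - 1
                    dsu.union(a, b)
                    edges.append((a, b, v))

    rater_of = np.concatenate(
        [np.full(m.n_objects, r, dtype=int) for r, m in enumerate(masks)]
    ) if n_nodes else np.zeros(0, dtype=int)
    iou_sum = np.zeros(n_nodes)
    for a, b, v in edges:
        iou_sum[a] += v
        iou_sum[b] += v

    clusters: dict[int, list[int]] = {}
    for node in range(n_nodes):
        clusters.setdefault(dsu.find(node), []).append(node)

    rows: list[int] = []  # n_i1 per object row
    for members in clusters.values():
        raters = [rater_of[m] for m in members]
        if len(set(raters)) < len(raters):
            # same rater contributed twice: keep the best-agreeing member,
            # demote the rest to singleton rows
            warnings.warn("cluster with two ROIs of one rater; keeping the higher-IoU member",
                          stacklevel=2)
            best: dict[int, int] = {}
            for m in members:
                r = rater_of[m]
                if r not in best or iou_sum[m] > iou_sum[best[r]]:
                    best[r] = m
            demoted = [m for m in members if m not in best.values()]
            rows.append(len(best))
            rows.extend([1] * len(demoted))
        else:
            rows.append(len(raters))

    n_obj_rows = len(rows)
    n_prop = n_obj_rows if n_proposals == "auto" else int(n_proposals)

    if n_prop > 0:
        rng = np.random.default_rng(seed)
        occupied = np.zeros(masks[0].shape, dtype=bool)
        for m in masks:
            occupied |= m.binary()
        areas = np.concatenate([m.areas() for m in masks]) if n_nodes else np.array([9])
        side = max(1, int(round(np.sqrt(np.median(areas)))))
        H, W = masks[0].shape
        placed = 0
        for _ in range(n_prop):
            for _attempt in range(1000):
                r0 = int(rng.integers(0, max(1, H - side + 1)))
                c0 = int(rng.integers(0, max(1, W - side + 1)))
                if not occupied[r0 : r0 + side, c0 : c0 + side].any():
                    occupied[r0 : r0 + side, c0 : c0 + side] = True
                    placed += 1
                    break
            else:
                warnings.warn("could not place all background proposals", stacklevel=2)
                break
        rows.extend([0] * placed)

    counts = np.column_stack([d - np.asarray(rows, dtype=int), np.asarray(rows, dtype=int)])
    flags = np.zeros(len(rows), dtype=bool)
    flags[n_obj_rows:] = True
    return AgreementTable(counts=counts, d=d, proposal_flags=flags)


def fleiss_kappa(table: AgreementTable) -> float:
    """Fleiss' kappa: (Pbar - Pbar_e) / (1 - Pbar_e).

    P_i = sum_j n_ij (n_ij - 1) / (d (d - 1)) over both classes, Pbar its
    mean over rows, p_j the class proportions and Pbar_e = sum_j p_j^2.
    Returns 1 for perfect unanimous agreement; NaN (with a warning) when
    chance agreement is exactly 1 but observed agreement is not.
    """
    n = table.counts
    d = table.d
    if len(n) < 1:
        raise ValueError("empty agreement table")
    if d < 2:
        raise ValueError("Fleiss' kappa needs d >= 2 raters")
    P_i = (n * (n - 1)).sum(axis=1) / (d * (d - 1))
    P_bar = float(P_i.mean())
    p_j = n.sum(axis=0) / (len(n) * d)
    P_e = float((p_j**2).sum())
    if P_e >= 1.0:
        if P_bar >= 1.0:
            return 1.0
        warnings.warn("chance agreement is 1 (single-class table); kappa undefined",
                      stacklevel=2)
        return float("nan")
    return (P_bar - P_e) / (1.0 - P_e)
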