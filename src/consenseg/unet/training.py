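"""Training machinery: augmentation, one-cycle fitting, checkpoint
selection, the expert-floor criterion and k-fold consensus ensembles.

Targets are estimated-ground-truth (or single-expert) masks; every
training sample is a (normalized image, binary target, pixel-weight map)
triple.  Tiles are drawn at random offsets from mirror-padded images,
augmented geometrically (flips, right-angle rotations, elastic
deformation by a smooth random displacement field applied identically to
image, mask and weights) and optimized with Adam under a one-cycle
learning-rate schedule: linear warm-up from lr_min to lr_max over the
first 30% of iterations, cosine anneal back to lr_min.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from ..io import Image2D, LabelMask
from ..metrics import evaluate_masks
from .model import Ensemble, UNet, UNetConfig, _mirror_pad, _normalize_input, predict_mask
from .weights import WeightMap, compute_weight_map, wce_gradient, weighted_cross_entropy

__all__ = [
    "augment",
    "one_cycle_lr",
    "fit_one_cycle",
    "select_model",
    "expert_floor_criterion",
    "train_consensus_ensemble",
]


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    weightmap: np.ndarray,
    seed: int | None = None,
    flip: bool = True,
    rotate: bool = True,
    elastic_alpha: float = 5.0,
    elastic_sigma: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one random geometric transform identically to all three rasters.

    The mask is resampled nearest-neighbor (stays binary/labelled); image
    and weights bilinearly.  Zero elastic magnitude plus disabled flips is
    the exact identity.  Deterministic given the seed.
    """
    if not (image.shape == mask.shape == weightmap.shape):
        raise ValueError("image, mask and weightmap must share a shape")
    rng = np.random.default_rng(seed)
    img, msk, wgt = image, mask, weightmap
    if flip and rng.random() < 0.5:
        img, msk, wgt = img[::-1], msk[::-1], wgt[::-1]
    if flip and rng.random() < 0.5:
        img, msk, wgt = img[:, ::-1], msk[:, ::-1], wgt[:, ::-1]
    if rotate:
        k = int(rng.integers(0, 4))
        if k:
            img, msk, wgt = np.rot90(img, k), np.rot90(msk, k), np.rot90(wgt, k)
    if elastic_alpha > 0:
        H, W = img.shape
        dr = ndimage.gaussian_filter(rng.standard_normal((H, W)), elastic_sigma)
        dc = ndimage.gaussian_filter(rng.standard_normal((H, W)), elastic_sigma)
        for d in (dr, dc):
            s = d.std()
            if s > 0:
                d *= elastic_alpha / s
        rr, cc = np.mgrid[0:H, 0:W].astype(float)
        coords = np.stack([rr + dr, cc + dc])
        img = ndimage.map_coordinates(img, coords, order=1, mode="reflect")
        wgt = ndimage.map_coordinates(wgt, coords, order=1, mode="reflect")
        msk = ndimage.map_coordinates(msk, coords, order=0, mode="reflect")
    return np.ascontiguousarray(img), np.ascontiguousarray(msk), np.ascontiguousarray(wgt)


def one_cycle_lr(
    it: int, n_iter: int, lr_min: float, lr_max: float, warm_frac: float = 0.3
) -> float:
    """lr(0) = lr(n_iter) = lr_min, peak lr_max at warm_frac * n_iter."""
    t1 = warm_frac * n_iter
    if it <= t1:
        return lr_min + (lr_max - lr_min) * (it / t1 if t1 > 0 else 1.0)
    return lr_min + (lr_max - lr_min) * 0.5 * (
        1.0 + math.cos(math.pi * (it - t1) / (n_iter - t1))
    )


@dataclass
class _PaddedSample:
    img: np.ndarray
    tgt: np.ndarray
    wgt: np.ndarray
    r_max: int
    c_max: int


def _prepare_sample(
    image: Image2D | np.ndarray, target: LabelMask, wm: WeightMap, cfg: UNetConfig
) -> _PaddedSample:
    x = _normalize_input(image)
    H, W = x.shape
    (ih, iw), (oh, ow) = cfg.in_tile, cfg.out_tile
    mh, mw = (ih - oh) // 2, (iw - ow) // 2
    eh, ew = max(0, oh - H), max(0, ow - W)
    pads = ((mh, mh + eh), (mw, mw + ew))
    return _PaddedSample(
        img=_mirror_pad(x, pads),
        tgt=_mirror_pad(target.binary().astype(np.float32), pads),
        wgt=_mirror_pad(wm.w.astype(np.float32), pads),
        r_max=max(0, H - oh),
        c_max=max(0, W - ow),
    )


def _n_tiles(shape: tuple[int, int], out_tile: tuple[int, int]) -> int:
    return math.ceil(shape[0] / out_tile[0]) * math.ceil(shape[1] / out_tile[1])


def median_f1(
    model: UNet | Ensemble,
    validation_set: list[tuple[Image2D | np.ndarray, LabelMask]],
    t: float = 0.5,
    min_size: int = 1,
) -> float:
    """Median over validation images of the detection F1 vs their targets."""
    scores = []
    for img, target in validation_set:
        pred = predict_mask(model, img, min_size=min_size)
        _, det = evaluate_masks(pred, target, t=t)
        scores.append(det.f1)
    return float(np.median(scores))


def fit_one_cycle(
    model: UNet,
    train_set: list[tuple[Image2D | np.ndarray, LabelMask, WeightMap]],
    lr_max: float = 4e-4,
    lr_min: float = 4e-5,
    n_iter: int = 972,
    batch: int = 4,
    seed: int | None = None,
    validation_set: list[tuple[Image2D | np.ndarray, LabelMask]] | None = None,
    checkpoint_every: int | None = None,
    t: float = 0.5,
    min_size: int = 1,
    augment_kwargs: dict | None = None,
) -> tuple[UNet, list[dict]]:
    """Train with Adam under the one-cycle policy; checkpoint per epoch.

    An epoch is one pass over the training tiles (the out-tile grid of all
    training images); ``checkpoint_every`` overrides the interval.  Each
    checkpoint stores a full weight snapshot and, when a validation set is
    given, its median per-image F1.  Returns the model at the final
    iteration plus the checkpoint list; per-iteration losses are kept on
    ``model.loss_history``.
    """
    if not train_set:
        raise ValueError("empty training set")
    cfg = model.config
    rng = np.random.default_rng(seed)
    samples = [_prepare_sample(img, tgt, wm, cfg) for img, tgt, wm in train_set]
    total_tiles = sum(
        _n_tiles(_normalize_input(img).shape, cfg.out_tile) for img, _, _ in train_set
    )
    if checkpoint_every is None:
        checkpoint_every = max(1, round(total_tiles / batch))
    (ih, iw), (oh, ow) = cfg.in_tile, cfg.out_tile
    mh, mw = (ih - oh) // 2, (iw - ow) // 2
    opt = model.make_optimizer(lr=lr_min)
    akw = augment_kwargs or {}
    losses: list[float] = []
    checkpoints: list[dict] = []
    model.loss_history = []
    model.training_log = []

    def snapshot(it: int, lr: float) -> None:
        entry = {
            "iteration": it,
            "lr": lr,
            "loss": float(np.mean(losses[-checkpoint_every:])) if losses else float("nan"),
            "val_median_f1": None,
        }
        if validation_set is not None:
            entry["val_median_f1"] = median_f1(model, validation_set, t=t, min_size=min_size)
        checkpoints.append(
            {"state": model.state_dict(), "iteration": it, "config": cfg,
             "val_median_f1": entry["val_median_f1"]}
        )
        model.training_log.append(entry)

    for it in range(1, n_iter + 1):
        xb, yb, wb = [], [], []
        for _ in range(batch):
            s = samples[int(rng.integers(0, len(samples)))]
            r0 = int(rng.integers(0, s.r_max + 1))
            c0 = int(rng.integers(0, s.c_max + 1))
            img_t = s.img[r0 : r0 + ih, c0 : c0 + iw]
            tgt_t = s.tgt[r0 : r0 + ih, c0 : c0 + iw]
            wgt_t = s.wgt[r0 : r0 + ih, c0 : c0 + iw]
            img_t, tgt_t, wgt_t = augment(
                img_t, tgt_t, wgt_t, seed=int(rng.integers(0, 2**31 - 1)), **akw
            )
            xb.append(img_t)
            yb.append(tgt_t[mh : mh + oh, mw : mw + ow])
            wb.append(wgt_t[mh : mh + oh, mw : mw + ow])
        x = np.stack(xb)[:, None]
        y = np.stack(yb)
        w = np.stack(wb)
        logits = model.forward(x, train=True)
        loss = weighted_cross_entropy(logits, y, w)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it} (non-finite loss); "
                f"log so far: {model.training_log}"
            )
        losses.append(loss)
        model.loss_history.append(loss)
        model.backward(wce_gradient(logits, y, w))
        opt.lr = one_cycle_lr(it, n_iter, lr_min, lr_max)
        opt.step(model.parameters(), model.gradients())
        if it % checkpoint_every == 0 or it == n_iter:
            snapshot(it, opt.lr)
    return model, checkpoints


def select_model(
    checkpoints: list[dict],
    validation_set: list[tuple[Image2D | np.ndarray, LabelMask]] | None = None,
    t: float = 0.5,
    min_size: int = 1,
) -> UNet:
    """Return the checkpoint with the highest validation median F1.

    Scores stored during training are reused unless a validation set is
    passed for (re-)evaluation.  Ties go to the later checkpoint.
    """
    if not checkpoints:
        raise ValueError("no checkpoints")
    best_idx, best_score = 0, -np.inf
    for i, ck in enumerate(checkpoints):
        if validation_set is not None:
            m = UNet(ck["config"])
            m.load_state_dict(ck["state"])
            score = median_f1(m, validation_set, t=t, min_size=min_size)
            ck = {**ck, "val_median_f1": score}
            checkpoints[i] = ck
        score = ck["val_median_f1"]
        if score is None:
            raise ValueError("checkpoints carry no validation scores; pass validation_set")
        if score >= best_score:  # >= : ties resolved to the later checkpoint
            best_idx, best_score = i, score
    ck = checkpoints[best_idx]
    model = UNet(ck["config"])
    model.load_state_dict(ck["state"])
    model.selected_iteration = ck["iteration"]
    model.selected_val_median_f1 = ck["val_median_f1"]
    return model


def expert_floor_criterion(
    model: UNet | Ensemble,
    validation_set: list[tuple[Image2D | np.ndarray, LabelMask]],
    expert_masks: list[list[LabelMask]],
    t: float = 0.5,
    min_size: int = 1,
) -> tuple[bool, pd.DataFrame]:
    """Does the model match the worst human expert on every validation image?

    For each image the model's F1 against the estimated ground truth must
    reach at least the minimum of the experts' F1 scores against the same
    reference.  Returns the verdict and a per-image report.
    """
    rows = []
    for (img, est_gt), experts in zip(validation_set, expert_masks):
        pred = predict_mask(model, img, min_size=min_size)
        _, det = evaluate_masks(pred, est_gt, t=t)
        floors = []
        for em in experts:
            _, edet = evaluate_masks(em, est_gt, t=t)
            floors.append(edet.f1)
        floor = min(floors) if floors else 0.0
        rows.append(
            {
                "model_f1": det.f1,
                "expert_floor_f1": floor,
                "passes": det.f1 >= floor,
            }
        )
    report = pd.DataFrame(rows)
    return bool(report["passes"].all()), report


def _stratified_folds(
    n: int, k: int, rng: np.random.Generator, groups: list[str] | None
) -> list[np.ndarray]:
    """k validation folds, stratified by group label when given."""
    if k == 1:
        return [np.arange(n)]
    folds: list[list[int]] = [[] for _ in range(k)]
    if groups is None:
        order = rng.permutation(n)
        for i, idx in enumerate(order):
            folds[i % k].append(int(idx))
    else:
        labels = np.asarray(groups)
        pos = 0
        for lab in pd.unique(labels):
            idxs = rng.permutation(np.flatnonzero(labels == lab))
            for idx in idxs:
                folds[pos % k].append(int(idx))
                pos += 1
    return [np.asarray(sorted(f)) for f in folds]


def train_consensus_ensemble(
    images: list[Image2D | np.ndarray],
    est_gt: list[LabelMask],
    k: int = 4,
    mode: str = "from_scratch",
    pretrained: UNet | dict | None = None,
    seed: int | None = None,
    config: UNetConfig | None = None,
    groups: list[str] | None = None,
    expert_masks: list[list[LabelMask]] | None = None,
    weight_params: dict | None = None,
    **fit_kwargs,
) -> Ensemble:
    """k-fold consensus training with checkpoint selection and ensembling.

    One model is trained per train/validation split (stratified by
    experimental group when known), selected by validation median F1, and
    checked against the expert floor when expert annotations are supplied.
    Modes: "from_scratch" (random init), "fine_tuned" (init from pretrained
    weights, then train), "frozen" (pretrained weights, evaluation only —
    zero gradient updates).  The ensemble averages member softmax maps.
    ``k=1`` degenerates to a single consensus model validated on its own
    training data.
    """
    if mode not in ("from_scratch", "fine_tuned", "frozen"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("fine_tuned", "frozen") and pretrained is None:
        raise ValueError(f"{mode} mode requires pretrained weights")
    if len(images) != len(est_gt):
        raise ValueError("images and est_gt must align")
    cfg = config or UNetConfig.mini_profile()
    rng = np.random.default_rng(seed)
    wparams = weight_params or {}
    wmaps = [compute_weight_map(m, **wparams) for m in est_gt]
    n = len(images)
    folds = _stratified_folds(n, k, rng, groups)
    pre_state = None
    if pretrained is not None:
        pre_state = pretrained.state_dict() if isinstance(pretrained, UNet) else pretrained

    members: list[UNet] = []
    reports: list[dict] = []
    for f, val_idx in enumerate(folds):
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        train_idx = np.flatnonzero(~val_mask) if k > 1 else np.arange(n)
        fold_cfg = dc_replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        model = UNet(fold_cfg)
        if pre_state is not None:
            model.load_state_dict(pre_state)
        validation = [(images[i], est_gt[i]) for i in val_idx]
        if mode == "frozen":
            selected = model
            selected.selected_val_median_f1 = median_f1(
                selected, validation, min_size=fit_kwargs.get("min_size", 1)
            )
        else:
            train = [(images[i], est_gt[i], wmaps[i]) for i in train_idx]
            _, checkpoints = fit_one_cycle(
                model,
                train,
                seed=int(rng.integers(0, 2**31 - 1)),
                validation_set=validation,
                **fit_kwargs,
            )
            selected = select_model(checkpoints)
        selected.provenance = mode
        report = {"fold": f, "val_median_f1": selected.selected_val_median_f1,
                  "meets_expert_floor": None}
        if expert_masks is not None:
            ok, _detail = expert_floor_criterion(
                selected,
                validation,
                [expert_masks[i] for i in val_idx],
                min_size=fit_kwargs.get("min_size", 1),
            )
            selected.meets_expert_floor = ok
            report["meets_expert_floor"] = ok
        members.append(selected)
        reports.append(report)
    ensemble = Ensemble(members)
    ensemble.fold_reports = reports
    return ensemble
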