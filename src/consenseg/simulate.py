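"""Seeded generators for fluorescence-like scenes and simulated raters.

The generator emulates the regime the pipeline targets: blob-like
fluorescent nuclei (isotropic Gaussian intensity profiles) on a noisy
background, with variable per-object signal-to-noise; annotators whose
miss probability rises as object intensity falls, who jitter object
boundaries and occasionally add false positives; noisy "model
predictions" standing in for trained networks; and two-group experiments
with a known density shift.

Default scene parameters mirror the imaging regime of the motivating
datasets — on average ~35 nuclei per frame, 1.61 px/µm, 8-bit dynamic
range after projection — scaled to a 256 x 256 desk-size frame.
Everything is deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Image2D, LabelMask, RegionMask, connected_components, write_image, write_mask

__all__ = [
    "SceneConfig",
    "AnnotatorProfile",
    "default_annotator_panel",
    "Experiment",
    "generate_scene",
    "simulate_annotator",
    "simulate_predictor",
    "generate_experiment",
    "write_experiment",
]


@dataclass
class SceneConfig:
    """Parameters of one synthetic fluorescence scene.

    ``radius`` is the half-maximum radius of the Gaussian blob profile and
    also the truth-mask radius; ``amplitude`` the peak intensity above
    background, sampled per object so the scene spans easy (bright) to
    ambiguous (dim) objects.
    """

    shape: tuple[int, int] = (256, 256)
    n_objects: int = 35
    radius: tuple[float, float] = (4.0, 8.0)
    amplitude: tuple[float, float] = (40.0, 120.0)
    background: float = 20.0
    noise_sigma: float = 8.0
    bit_depth: int = 8
    px_per_um: float = 1.61
    min_gap: float = 2.0
    seed: int | None = None


@dataclass
class AnnotatorProfile:
    """Noise model of one simulated expert.

    Detection probability is a logistic function of the object's mean
    intensity above background (midpoint/width in bit-value units), so dim
    objects are missed more often — the inter-rater variability pattern
    seen in real multi-expert annotations.  Kept objects get boundary
    jitter (a smooth random perturbation of the signed distance to the
    object boundary, std ``boundary_jitter`` px) and a constant
    ``dilation_bias`` (px, positive = over-segmenting rater).  False
    positives appear as dim spurious blobs, ``fp_rate`` expected per image.
    """

    midpoint: float = 30.0
    width: float = 12.0
    boundary_jitter: float = 1.0
    fp_rate: float = 1.0
    dilation_bias: float = 0.0
    rater_id: str = "sim"
    seed: int | None = None
    miss_curve: Callable[[float], float] | None = None

    def detection_probability(self, mean_intensity: float) -> float:
        if self.miss_curve is not None:
            return float(np.clip(1.0 - self.miss_curve(mean_intensity), 0.0, 1.0))
        return float(1.0 / (1.0 + np.exp(-(mean_intensity - self.midpoint) / self.width)))


def default_annotator_panel(n: int = 3, seed: int | None = None) -> list[AnnotatorProfile]:
    """A panel of n plausibly-noisy experts with distinct biases and seeds.

    The panel's noise level (logistic detection midpoint 20 / width 12 above
    background, 2 px boundary jitter, 2 false positives per image, slight
    over-/under-segmentation biases) is chosen so that individual raters make
    visible, intensity-dependent errors on default scenes while majority
    agreement still identifies most objects — the regime in which consensus
    estimation is useful at all.
    """
    rng = np.random.default_rng(seed)
    biases = [-0.5, 0.0, 0.5]
    return [
        AnnotatorProfile(
            midpoint=20.0,
            width=8.0,
            boundary_jitter=2.0,
            fp_rate=2.0,
            dilation_bias=biases[i % len(biases)],
            rater_id=f"expert{i + 1}",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i in range(n)
    ]


def _place_centers(rng: np.random.Generator, cfg: SceneConfig, radii: np.ndarray) -> np.ndarray:
    H, W = cfg.shape
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        lo = r + 1
        for _attempt in range(400):
            y = rng.uniform(lo, H - lo)
            x = rng.uniform(lo, W - lo)
            ok = all(
                np.hypot(y - cy, x - cx) >= r + radii[j] + cfg.min_gap
                for j, (cy, cx) in enumerate(centers)
            )
            if ok:
                centers.append((y, x))
                break
        else:
            raise RuntimeError(
                f"could not place object {i + 1}/{len(radii)}: "
                "reduce n_objects or radius for this frame size"
            )
    return np.asarray(centers)


def generate_scene(cfg: SceneConfig) -> tuple[Image2D, LabelMask, RegionMask]:
    """Render a scene: noisy image, noiseless-truth label mask, full-frame region."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape
    clean = np.zeros((H, W))
    truth = np.zeros((H, W), dtype=np.int32)
    if cfg.n_objects > 0:
        radii = rng.uniform(*cfg.radius, size=cfg.n_objects)
        amps = rng.uniform(*cfg.amplitude, size=cfg.n_objects)
        centers = _place_centers(rng, cfg, radii)
        for k, ((cy, cx), r, a) in enumerate(zip(centers, radii, amps), start=1):
            # render each blob into a local window (profile is negligible beyond 4r)
            ext = int(np.ceil(4 * r))
            r0, r1 = max(0, int(cy) - ext), min(H, int(cy) + ext + 1)
            c0, c1 = max(0, int(cx) - ext), min(W, int(cx) + ext + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
            sigma = r / np.sqrt(2.0 * np.log(2.0))  # half-maximum at radius r
            clean[r0:r1, c0:c1] += a * np.exp(-rho2 / (2.0 * sigma**2))
            truth[r0:r1, c0:c1][rho2 <= r**2] = k
    noisy = cfg.background + clean + rng.normal(0.0, cfg.noise_sigma, size=(H, W))
    maxval = 2**cfg.bit_depth - 1
    pixels = np.clip(np.round(noisy), 0, maxval).astype(
        np.uint8 if cfg.bit_depth == 8 else np.uint16
    )
    image = Image2D(pixels, bit_depth=cfg.bit_depth, px_per_um=cfg.px_per_um, id="scene")
    return image, LabelMask(truth, annotator_id="truth"), RegionMask(np.ones((H, W), bool))


def _smooth_unit_noise(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Gaussian-correlated random field rescaled to unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr)
    s = f.std()
    return f / s if s > 0 else f


def _jitter_object(
    rng: np.random.Generator, obj: np.ndarray, sigma: float, bias: float
) -> np.ndarray:
    """Perturb an object's boundary via its signed distance transform."""
    if sigma <= 0 and bias == 0:
        return obj
    signed = ndimage.distance_transform_edt(obj) - ndimage.distance_transform_edt(~obj)
    field = _smooth_unit_noise(rng, obj.shape, 2.0) * sigma if sigma > 0 else 0.0
    out = (signed + field + bias) > 0
    if not out.any():
        return out
    # boundary noise may split the object: keep the largest 8-connected piece
    lab, n = ndimage.label(out, structure=np.ones((3, 3), bool))
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        out = lab == (int(np.argmax(sizes)) + 1)
    return out


def simulate_annotator(
    truth: LabelMask,
    image: Image2D,
    profile: AnnotatorProfile,
    seed: int | None = None,
    background: float = 20.0,
) -> LabelMask:
    """One simulated expert's annotation of a scene."""
    if truth.shape != image.shape:
        raise ValueError("truth and image must share a shape")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    H, W = truth.shape
    canvas = np.zeros((H, W), dtype=np.int32)
    nxt = 1
    pix = image.pixels.astype(float)
    slices = ndimage.find_objects(truth.labels)
    for k, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        obj_local = truth.labels[sl] == k
        mean_int = float(pix[sl][obj_local].mean()) - background
        if rng.random() >= profile.detection_probability(mean_int):
            continue  # missed (dim) object
        pad = int(np.ceil(3 * profile.boundary_jitter + abs(profile.dilation_bias))) + 2
        r0, c0 = max(sl[0].start - pad, 0), max(sl[1].start - pad, 0)
        r1, c1 = min(sl[0].stop + pad, H), min(sl[1].stop + pad, W)
        patch = truth.labels[r0:r1, c0:c1] == k
        jittered = _jitter_object(rng, patch, profile.boundary_jitter, profile.dilation_bias)
        if jittered.any():
            target = canvas[r0:r1, c0:c1]
            target[jittered] = nxt  # overlapping annotations: last writer wins
            nxt += 1
    # false positives: dim spurious blobs in the background
    n_fp = rng.poisson(profile.fp_rate)
    areas = truth.areas()
    r_fp = max(2.0, 0.7 * np.sqrt(np.median(areas) / np.pi)) if len(areas) else 3.0
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n_fp):
        for _attempt in range(100):
            cy, cx = rng.uniform(r_fp, H - r_fp), rng.uniform(r_fp, W - r_fp)
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_fp**2
            if not (truth.labels[blob] > 0).any() and not (canvas[blob] > 0).any():
                canvas[blob] = nxt
                nxt += 1
                break
    return connected_components(canvas > 0, annotator_id=profile.rater_id)


def simulate_predictor(
    truth: LabelMask, quality: float, seed: int | None = None
) -> np.ndarray:
    """Softmax-like foreground probability map of a virtual trained model.

    A convex mix of the (slightly blurred) truth and a spatially correlated
    noise field; the mixing weight is 1 - quality, so ``quality=1``
    reproduces the truth exactly and ``quality=0`` is pure noise.
    Independent seeds give independent predictors whose argmax masks can be
    ensembled by probability averaging.
    """
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    beta = 1.0 - quality
    base = truth.binary().astype(float)
    if beta > 0:
        base = ndimage.gaussian_filter(base, 1.5 * beta)
    noise = 0.5 + 0.6 * _smooth_unit_noise(rng, truth.shape, 2.0)
    return np.clip((1.0 - beta) * base + beta * noise, 0.0, 1.0)


@dataclass
class Experiment:
    """Two-or-more-group synthetic experiment with known density effect."""

    images: list[Image2D]
    truths: list[LabelMask]
    regions: list[RegionMask]
    table: pd.DataFrame  # columns: image_id, group
    expected_multipliers: dict[str, float] = field(default_factory=dict)


def generate_experiment(
    groups: list[tuple[str, int, float]],
    base: SceneConfig | None = None,
    seed: int | None = None,
) -> Experiment:
    """Generate per-group scenes with object counts scaled by the multipliers.

    ``groups`` is a list of (label, n_images, density multiplier); per-image
    counts are Poisson around multiplier * base.n_objects, mimicking
    image-to-image biological variability.
    """
    base = base or SceneConfig()
    rng = np.random.default_rng(seed)
    images, truths, regions, rows = [], [], [], []
    mults = {}
    for label, n_images, mult in groups:
        if mult <= 0:
            raise ValueError("density multipliers must be > 0")
        mults[label] = mult
        for i in range(n_images):
            n_obj = int(rng.poisson(mult * base.n_objects))
            cfg = SceneConfig(**{**asdict(base), "n_objects": n_obj,
                                 "seed": int(rng.integers(0, 2**31 - 1))})
            img, truth, region = generate_scene(cfg)
            img.id = f"{label}_{i:03d}"
            images.append(img)
            truths.append(truth)
            regions.append(region)
            rows.append({"image_id": img.id, "group": label})
    return Experiment(images, truths, regions, pd.DataFrame(rows), mults)


def write_experiment(exp: Experiment, outdir: str | Path, provenance: dict | None = None) -> None:
    """Write images/, masks/, regions/, groups.csv (+ provenance.json) to disk."""
    outdir = Path(outdir)
    for sub in ("images", "masks", "regions"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for img, truth, region in zip(exp.images, exp.truths, exp.regions):
        write_image(img, outdir / "images" / f"{img.id}.tif")
        write_mask(truth, outdir / "masks" / f"{img.id}.tif")
        write_mask(LabelMask(region.mask.astype(np.int32)), outdir / "regions" / f"{img.id}.tif")
    exp.table.to_csv(outdir / "groups.csv", index=False)
    if provenance is not None:
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
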