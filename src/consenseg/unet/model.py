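"""Unpadded U-Net construction, overlap-tile inference and ensembling.

The encoder is VGG-like: ``depth`` convolutional modules of two unpadded
3x3 convolutions, each followed by a leaky ReLU (leak 0.1); every module
except the last (the bottleneck) ends in a 2x2 stride-2 max-pool.  The
decoder mirrors it with 2x2 transposed convolutions, concatenation of the
center-cropped encoder feature map, and two 3x3 convolutions.  Batch
normalization follows every (up-)convolution below the first level, so an
unnormalized path from input to output remains for absolute intensities.
A final 1x1 convolution produces two-class scores; softmax is applied
outside the loss.

Because all convolutions are valid, an in-tile of side ``s`` maps to an
out-tile of side ``s - 184`` at depth 5 (540 -> 356); the paper profile
and a CPU-sized mini profile (depth 3, 140 -> 100) are provided.
Arbitrary image sizes are handled by the overlap-tile strategy: mirror
padding by the context margin and seamless stitching of out-tiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..io import Image2D, LabelMask, connected_components, filter_min_size
from .nn import Adam, BatchNorm, Conv1x1, Conv3x3, LeakyReLU, MaxPool2, UpConv2x2

__all__ = ["UNetConfig", "UNet", "Ensemble", "build_unet", "tile_predict", "predict_mask",
           "save_model", "load_model"]


def unet_shape_arithmetic(in_side: int, depth: int) -> tuple[int, list[int]]:
    """Valid-convolution shape walk; returns (out_side, encoder skip sides).

    Raises with the first offending level if a pooled size turns odd or a
    feature map shrinks away.
    """
    s = in_side
    skips: list[int] = []
    for level in range(depth - 1):
        s -= 4
        if s < 1:
            raise ValueError(f"encoder level {level}: feature map exhausted (side {s})")
        skips.append(s)
        if s % 2:
            raise ValueError(
                f"encoder level {level}: side {s} is odd before pooling; "
                "choose an in_tile compatible with the depth"
            )
        s //= 2
    s -= 4  # bottleneck module
    if s < 1:
        raise ValueError(f"bottleneck: feature map exhausted (side {s})")
    for level in range(depth - 2, -1, -1):
        s = 2 * s - 4
        if s < 1:
            raise ValueError(f"decoder level {level}: feature map exhausted (side {s})")
    return s, skips


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts encoder convolutional modules including the unpooled
    bottleneck (the published network has depth 5).  ``out_tile`` is
    derived from ``in_tile`` by valid-convolution arithmetic and checked at
    construction.
    """

    depth: int = 5
    base_filters: int = 64
    leak: float = 0.1
    in_tile: tuple[int, int] = (540, 540)
    batch_norm: bool = True
    seed: int = 0
    out_tile: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        oh, _ = unet_shape_arithmetic(self.in_tile[0], self.depth)
        ow, _ = unet_shape_arithmetic(self.in_tile[1], self.depth)
        self.out_tile = (oh, ow)

    @property
    def margin(self) -> int:
        return (self.in_tile[0] - self.out_tile[0]) // 2

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "UNetConfig":
        return cls(depth=5, base_filters=64, in_tile=(540, 540), seed=seed)

    @classmethod
    def mini_profile(cls, seed: int = 0) -> "UNetConfig":
        """CPU-scale test profile: depth 3, base 16 filters, 140 -> 100."""
        return cls(depth=3, base_filters=16, in_tile=(140, 140), seed=seed)


class UNet:
    """Trainable unpadded U-Net with two output classes."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.provenance = "from_scratch"
        self.training_log: list[dict] = []
        rng = np.random.default_rng(config.seed)
        d, base, bn = config.depth, config.base_filters, config.batch_norm
        ch = [base * 2**m for m in range(d)]

        self.enc: list[dict] = []
        cin = 1
        for m in range(d):
            use_bn = bn and m > 0  # below the first level only
            mod = {
                "conv1": Conv3x3(cin, ch[m], rng),
                "bn1": BatchNorm(ch[m]) if use_bn else None,
                "act1": LeakyReLU(config.leak),
                "conv2": Conv3x3(ch[m], ch[m], rng),
                "bn2": BatchNorm(ch[m]) if use_bn else None,
                "act2": LeakyReLU(config.leak),
                "pool": MaxPool2() if m < d - 1 else None,
            }
            self.enc.append(mod)
            cin = ch[m]

        self.dec: list[dict] = []
        for level in range(d - 2, -1, -1):
            use_bn = bn and level > 0
            mod = {
                "up": UpConv2x2(cin, ch[level], rng),
                "bn_up": BatchNorm(ch[level]) if use_bn else None,
                "act_up": LeakyReLU(config.leak),
                "conv1": Conv3x3(2 * ch[level], ch[level], rng),
                "bn1": BatchNorm(ch[level]) if use_bn else None,
                "act1": LeakyReLU(config.leak),
                "conv2": Conv3x3(ch[level], ch[level], rng),
                "bn2": BatchNorm(ch[level]) if use_bn else None,
                "act2": LeakyReLU(config.leak),
            }
            self.dec.append(mod)
            cin = ch[level]
        self.head = Conv1x1(cin, 2, rng)
        self._layers = self._collect_layers()

    # -- parameter bookkeeping -------------------------------------------------
    def _collect_layers(self) -> dict[str, object]:
        layers: dict[str, object] = {}
        for m, mod in enumerate(self.enc):
            for key, layer in mod.items():
                if layer is not None and hasattr(layer, "params"):
                    layers[f"enc{m}.{key}"] = layer
        for l, mod in enumerate(self.dec):
            for key, layer in mod.items():
                if layer is not None and hasattr(layer, "params"):
                    layers[f"dec{l}.{key}"] = layer
        layers["head"] = self.head
        return layers

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, layer in self._layers.items()
            for p, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, layer in self._layers.items()
            for p, arr in layer.grads.items()
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for name, layer in self._layers.items():
            if isinstance(layer, BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in state.items():
            if k.endswith(".running_mean") or k.endswith(".running_var"):
                name, attr = k.rsplit(".", 1)
                setattr(self._layers[name], attr, v.copy())
            else:
                if params[k].shape != v.shape:
                    raise ValueError(f"shape mismatch for parameter {k}")
                params[k][...] = v

    # -- forward / backward ----------------------------------------------------
    @staticmethod
    def _crop_center(x: np.ndarray, h: int, w: int) -> np.ndarray:
        dh = (x.shape[2] - h) // 2
        dw = (x.shape[3] - w) // 2
        return x[:, :, dh : dh + h, dw : dw + w]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) normalized intensities -> logits (N, 2, Ho, Wo)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        skips = []
        self._skip_meta: list[tuple[tuple[int, int], tuple[int, int]]] = []
        for m, mod in enumerate(self.enc):
            for key in ("conv1", "bn1", "act1", "conv2", "bn2", "act2"):
                if mod[key] is not None:
                    x = mod[key].forward(x, train)
            if mod["pool"] is not None:
                skips.append(x)
                x = mod["pool"].forward(x, train)
        self._skips_shapes = [s.shape for s in skips]
        for l, mod in enumerate(self.dec):
            x = mod["up"].forward(x, train)
            if mod["bn_up"] is not None:
                x = mod["bn_up"].forward(x, train)
            x = mod["act_up"].forward(x, train)
            skip = skips.pop()
            cropped = self._crop_center(skip, x.shape[2], x.shape[3])
            x = np.concatenate([cropped, x], axis=1)
            for key in ("conv1", "bn1", "act1", "conv2", "bn2", "act2"):
                if mod[key] is not None:
                    x = mod[key].forward(x, train)
        return self.head.forward(x, train)

    def forward_softmax(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode per-pixel class probabilities (N, 2, Ho, Wo)."""
        logits = self.forward(x, train=False)
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips: list[np.ndarray] = []
        for l in range(len(self.dec) - 1, -1, -1):
            mod = self.dec[l]
            for key in ("act2", "bn2", "conv2", "act1", "bn1", "conv1"):
                if mod[key] is not None:
                    dx = mod[key].backward(dx)
            nskip = dx.shape[1] // 2
            dskip_cropped, dx = dx[:, :nskip], dx[:, nskip:]
            dskips.append(dskip_cropped)
            dx = mod["act_up"].backward(dx)
            if mod["bn_up"] is not None:
                dx = mod["bn_up"].backward(dx)
            dx = mod["up"].backward(dx)
        for m in range(len(self.enc) - 1, -1, -1):
            mod = self.enc[m]
            if mod["pool"] is not None:
                dx = mod["pool"].backward(dx)
                dskip_cropped = dskips.pop()  # deepest skip was appended last
                full = np.zeros(self._skips_shapes[m], dtype=dx.dtype)
                h, w = dskip_cropped.shape[2], dskip_cropped.shape[3]
                dh = (full.shape[2] - h) // 2
                dw = (full.shape[3] - w) // 2
                full[:, :, dh : dh + h, dw : dw + w] = dskip_cropped
                dx = dx + full
            for key in ("act2", "bn2", "conv2", "act1", "bn1", "conv1"):
                if mod[key] is not None:
                    dx = mod[key].backward(dx)

    def make_optimizer(self, lr: float = 4e-4) -> Adam:
        return Adam(lr=lr)


def build_unet(config: UNetConfig) -> UNet:
    """Construct an untrained network; fails loudly on bad shape arithmetic."""
    return UNet(config)


class Ensemble:
    """Softmax-averaging ensemble of k member networks."""

    def __init__(self, members: list[UNet]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    @property
    def config(self) -> UNetConfig:
        return self.members[0].config

    def forward_softmax(self, x: np.ndarray) -> np.ndarray:
        out = self.members[0].forward_softmax(x)
        for m in self.members[1:]:
            out += m.forward_softmax(x)
        return out / len(self.members)


def _mirror_pad(arr: np.ndarray, pads: tuple[tuple[int, int], tuple[int, int]]) -> np.ndarray:
    """np.pad(symmetric), applied repeatedly so pads may exceed the array size."""
    out = arr
    pads = [list(p) for p in pads]
    while any(p[0] > 0 or p[1] > 0 for p in pads):
        step = []
        for ax, p in enumerate(pads):
            cap = out.shape[ax] - 1
            a, b = min(p[0], cap), min(p[1], cap)
            p[0] -= a
            p[1] -= b
            step.append((a, b))
        out = np.pad(out, step, mode="symmetric")
    return out


def _normalize_input(image: Image2D | np.ndarray) -> np.ndarray:
    if isinstance(image, Image2D):
        return image.pixels.astype(np.float32) / (2**image.bit_depth - 1)
    return np.asarray(image, dtype=np.float32)


def tile_predict(model: UNet | Ensemble, image: Image2D | np.ndarray) -> np.ndarray:
    """Overlap-tile inference: (2, H, W) softmax map for any image size.

    The image is mirror-padded by the context margin, out-tiles are
    predicted on a grid covering the image and stitched; ensembles average
    member softmax maps.
    """
    x = _normalize_input(image)
    H, W = x.shape
    cfg = model.config
    (ih, iw), (oh, ow) = cfg.in_tile, cfg.out_tile
    mh, mw = (ih - oh) // 2, (iw - ow) // 2

    def starts(total: int, out: int) -> list[int]:
        if total <= out:
            return [0]
        s = list(range(0, total - out + 1, out))
        if s[-1] + out < total:
            s.append(total - out)
        return s

    rs, cs = starts(H, oh), starts(W, ow)
    pad_b = max(0, rs[-1] + oh - H)
    pad_r = max(0, cs[-1] + ow - W)
    padded = _mirror_pad(x, ((mh, mh + pad_b), (mw, mw + pad_r)))
    out = np.zeros((2, H, W), dtype=np.float32)
    for r0 in rs:
        for c0 in cs:
            tile = padded[r0 : r0 + ih, c0 : c0 + iw]
            soft = model.forward_softmax(tile[None, None])[0]
            h = min(oh, H - r0)
            w = min(ow, W - c0)
            out[:, r0 : r0 + h, c0 : c0 + w] = soft[:, :h, :w]
    return out


def predict_mask(model: UNet | Ensemble, image: Image2D | np.ndarray,
                 min_size: int = 1) -> LabelMask:
    """Argmax the softmax map, component-label and size-filter."""
    soft = tile_predict(model, image)
    mask = connected_components(soft[1] > soft[0])
    return filter_min_size(mask, min_size) if min_size > 1 else mask


def save_model(model: UNet, path: str | Path) -> None:
    """Weights to .npz with a JSON config sidecar."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    cfg = asdict(model.config)
    cfg.pop("out_tile", None)
    sidecar = {"config": cfg, "provenance": model.provenance,
               "training_log": model.training_log}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["config"]
    cfg["in_tile"] = tuple(cfg["in_tile"])
    model = UNet(UNetConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    model.provenance = sidecar.get("provenance", "from_scratch")
    model.training_log = sidecar.get("training_log", [])
    return model
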