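"""Four encoder–decoder segmentation architectures and their training loop.

All four networks share the U-shape: an encoder of convolutional stages, each
followed by 2x2 max pooling, and a decoder that restores full resolution.
They differ in how the encoder stacks convolutions and how the decoder gets
its spatial detail back:

* ``vgg11_unet`` / ``vgg16_unet`` — plain VGG-style conv stacks (1,1,2,...
  resp. 2,2,3,... convolutions per stage), decoder with nearest-neighbour
  upsampling and skip concatenations from the encoder, as in TernausNet.
* ``segnet`` — a VGG-16-style encoder whose decoder *unpools* through the
  memorised max-pooling indices of the matching encoder stage; there are no
  encoder–decoder concatenation paths.
* ``albunet`` — residual blocks (ResNet-style) in the encoder, U-Net decoder
  with skip concatenations.

The loss is the sum of the Soft Dice loss and binary cross-entropy computed
from logits, optimised with Adam.  Capacity is configurable down to "toy"
scale (depth 3, few base channels, 128x128 inputs) so that all four models
train from scratch on phantom cohorts on a single CPU in minutes.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit
from skimage.transform import resize

from .errors import ContractError, DataError, ParameterError
from .nn import Adam, Conv2d, ConvStack, MaxPool2x2, MaxUnpool2x2, ResBlock, UpsampleNearest2x
from .phantom import SegmentationSample

__all__ = [
    "ARCHITECTURES",
    "ModelConfig",
    "TrainConfig",
    "toy_config",
    "toy_train_config",
    "SegmentationModel",
    "build_model",
    "loss_dice_bce",
    "train",
    "predict_masks",
    "count_parameters",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("vgg11_unet", "vgg16_unet", "segnet", "albunet")

# Convolutions per encoder stage in the full VGG layouts; truncated to `depth`.
_VGG11_STAGES = (1, 1, 2, 2, 2)
_VGG16_STAGES = (2, 2, 3, 3, 3)

DICE_EPS = 1.0  # smoothing term of the Soft Dice loss


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "albunet"
    base_channels: int = 8
    depth: int = 3
    in_size: int = 128
    heads: str = "both"  # {"lung", "heart", "both"}

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ParameterError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.depth < 2:
            raise ParameterError("depth must be >= 2")
        if self.in_size % (2 ** self.depth) != 0:
            raise ParameterError(
                f"in_size {self.in_size} not divisible by 2^depth = {2 ** self.depth}"
            )
        if self.heads not in ("lung", "heart", "both"):
            raise ParameterError(f"heads must be lung/heart/both, got {self.heads!r}")

    @property
    def out_channels(self) -> int:
        return 2 if self.heads == "both" else 1


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe.  Defaults are the full-scale recipe (Adam, batch 8,
    75 epochs, initial learning rate 1e-4); toy presets shrink epochs and
    raise the rate for short from-scratch runs but never change the loss."""

    batch_size: int = 8
    epochs: int = 75
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    loss: str = "dice_plus_bce"
    seed: int = 0
    augment: bool = False

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ParameterError("only the adam optimizer is provided")
        if self.loss != "dice_plus_bce":
            raise ParameterError("only the dice_plus_bce loss is provided")
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ParameterError("batch_size/epochs/learning_rate out of range")


# Desk-scale capacity/recipe presets, per architecture.  SegNet's decoder has
# no skip connections, and VGG-11's encoder stacks only one conv in its first
# two stages; both need extra width to place boundaries precisely, so their
# toy presets are wider (SegNet additionally trains with a hotter rate).
_TOY_BASE = {"vgg11_unet": 12, "vgg16_unet": 8, "albunet": 8, "segnet": 16}
_TOY_EPOCHS = {"vgg11_unet": 10, "vgg16_unet": 8, "albunet": 8, "segnet": 8}
_TOY_LR = {"vgg11_unet": 1e-3, "vgg16_unet": 1e-3, "albunet": 1e-3, "segnet": 2e-3}


def toy_config(architecture: str) -> ModelConfig:
    """Desk-scale preset: depth 3, 128x128 inputs, few base channels."""
    return ModelConfig(
        architecture=architecture,
        base_channels=_TOY_BASE.get(architecture, 8),
        depth=3,
        in_size=128,
    )


def toy_train_config(architecture: str = "albunet", seed: int = 0,
                     epochs: int | None = None) -> TrainConfig:
    """Short from-scratch recipe paired with :func:`toy_config`."""
    return TrainConfig(
        batch_size=8,
        epochs=_TOY_EPOCHS.get(architecture, 8) if epochs is None else epochs,
        learning_rate=_TOY_LR.get(architecture, 1e-3),
        seed=seed,
    )


class SegmentationModel:
    """One of the four architectures, assembled from the nn layer kit."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        arch, b, d = config.architecture, config.base_channels, config.depth
        widths = [b * 2 ** s for s in range(d)]
        self._widths = widths
        self._style = "segnet" if arch == "segnet" else "unet"

        if arch in ("vgg11_unet", "vgg16_unet"):
            counts = (_VGG11_STAGES if arch == "vgg11_unet" else _VGG16_STAGES)[:d]
            make_block = lambda cin, cout, s: ConvStack(cin, cout, counts[s], rng, dtype)
        elif arch == "segnet":
            counts = _VGG16_STAGES[:d]
            make_block = lambda cin, cout, s: ConvStack(cin, cout, counts[s], rng, dtype)
        else:  # albunet
            make_block = lambda cin, cout, s: ResBlock(cin, cout, rng, dtype)

        self.enc_blocks, self.pools = [], []
        cin = 1
        for s in range(d):
            self.enc_blocks.append(make_block(cin, widths[s], s))
            self.pools.append(MaxPool2x2())
            cin = widths[s]

        if self._style == "segnet":
            # keep channel count through the bottleneck so unpooling indices match
            self.bottleneck = ConvStack(widths[-1], widths[-1], 1, rng, dtype)
            self.unpools = [MaxUnpool2x2() for _ in range(d)]
            self.dec_blocks = []
            counts_rev = list(reversed(counts))
            for s in reversed(range(d)):  # deepest decoder stage first
                cout = widths[s - 1] if s >= 1 else widths[0]
                self.dec_blocks.append(
                    ConvStack(widths[s], cout, counts_rev[d - 1 - s], rng, dtype)
                )
            head_in = widths[0]
        else:
            wb = b * 2 ** d
            if arch == "albunet":
                self.bottleneck = ResBlock(widths[-1], wb, rng, dtype)
            else:
                self.bottleneck = ConvStack(widths[-1], wb, 1, rng, dtype)
            self.ups = [UpsampleNearest2x() for _ in range(d)]
            self.dec_blocks = []
            c_deep = wb
            for s in reversed(range(d)):  # deepest decoder stage first
                self.dec_blocks.append(ConvStack(c_deep + widths[s], widths[s], 1, rng, dtype))
                c_deep = widths[s]
            head_in = widths[0]

        self.head = Conv2d(head_in, config.out_channels, k=1, pad=0, rng=rng, dtype=dtype)

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[dict]:
        blocks = list(self.enc_blocks) + [self.bottleneck] + list(self.dec_blocks) + [self.head]
        return [p for blk in blocks for p in blk.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p["grad"][...] = 0.0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) -> logits (N, out_channels, H, W); H = W = in_size."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ContractError(f"expected (N, 1, H, W) input, got {x.shape}")
        if x.shape[2] != self.config.in_size or x.shape[3] != self.config.in_size:
            raise ContractError(
                f"spatial size {x.shape[2:]} != configured in_size {self.config.in_size}"
            )
        x = x.astype(self.dtype, copy=False)
        d = self.config.depth
        self._skips = []
        for s in range(d):
            x = self.enc_blocks[s].forward(x)
            self._skips.append(x)
            x = self.pools[s].forward(x)
        x = self.bottleneck.forward(x)
        if self._style == "segnet":
            for i, s in enumerate(reversed(range(d))):
                x = self.unpools[i].forward(x, self.pools[s].indices)
                x = self.dec_blocks[i].forward(x)
        else:
            self._split = []
            for i, s in enumerate(reversed(range(d))):
                x = self.ups[i].forward(x)
                skip = self._skips[s]
                self._split.append(x.shape[1])
                x = np.concatenate([x, skip], axis=1)
                x = self.dec_blocks[i].forward(x)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        d = self.config.depth
        g = self.head.backward(g)
        skip_grads = [None] * d
        if self._style == "segnet":
            for i in reversed(range(d)):
                g = self.dec_blocks[i].backward(g)
                g = self.unpools[i].backward(g)
        else:
            for i in reversed(range(d)):
                s = d - 1 - i  # encoder stage whose skip fed dec_blocks[i]
                g = self.dec_blocks[i].backward(g)
                c_up = self._split[i]
                g_up, g_skip = g[:, :c_up], g[:, c_up:]
                skip_grads[s] = g_skip
                g = self.ups[i].backward(np.ascontiguousarray(g_up))
        g = self.bottleneck.backward(g)
        for s in reversed(range(d)):
            g = self.pools[s].backward(g)
            if skip_grads[s] is not None:
                g = g + skip_grads[s]
            g = self.enc_blocks[s].backward(g)


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> SegmentationModel:
    """Assemble a segmentation model; the seed fixes the weight initialisation."""
    return SegmentationModel(config, seed=seed, dtype=dtype)


def count_parameters(model: SegmentationModel) -> int:
    return int(sum(p["value"].size for p in model.params()))


# ---------------------------------------------------------------------------
# Loss: Soft Dice + binary cross-entropy, both from logits.

def _bce_with_logits(z: np.ndarray, t: np.ndarray) -> float:
    # stable: max(z,0) - z t + log(1 + exp(-|z|))
    return float(np.mean(np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))))


def loss_dice_bce(logits: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss plus mean binary cross-entropy, computed from logits.

    Dice is averaged per sample and per channel:
    ``1 - (2 Σ p t + eps) / (Σ p + Σ t + eps)`` with ``p = sigmoid(logits)``.
    """
    loss, _ = _loss_and_grad(np.asarray(logits, dtype=np.float64),
                             np.asarray(target, dtype=np.float64), eps, want_grad=False)
    return loss


def _loss_and_grad(logits, target, eps: float = DICE_EPS, want_grad: bool = True):
    z = logits
    t = target
    if z.shape != t.shape:
        raise ContractError(f"logits shape {z.shape} != target shape {t.shape}")
    if z.ndim == 2:
        z = z[None, None]
        t = t[None, None]
    elif z.ndim == 3:
        z = z[:, None]
        t = t[:, None]
    n, c = z.shape[:2]
    p = expit(z)
    axes = (2, 3)
    s_pt = (p * t).sum(axis=axes)
    s_p = p.sum(axis=axes)
    s_t = t.sum(axis=axes)
    denom = s_p + s_t + eps
    dice = 1.0 - (2.0 * s_pt + eps) / denom
    loss = float(dice.mean()) + _bce_with_logits(z, t)
    if not want_grad:
        return loss, None
    # d(dice)/dp, then chain through the sigmoid; BCE grad is (p - t)/Nel.
    num = 2.0 * s_pt + eps
    ddice_dp = -(2.0 * t * denom[..., None, None] - num[..., None, None]) / denom[..., None, None] ** 2
    dz = ddice_dp * p * (1.0 - p) / (n * c)
    dz += (p - t) / z.size
    if logits.ndim == 2:
        dz = dz[0, 0]
    elif logits.ndim == 3:
        dz = dz[:, 0]
    return loss, dz


# ---------------------------------------------------------------------------
# Data plumbing, training and inference.

def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return np.asarray(img, dtype=np.float64)
    return resize(img, (size, size), order=1, anti_aliasing=True, preserve_range=True)


def _resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    if mask.shape == (size, size):
        return mask > 0
    return resize(mask.astype(float), (size, size), order=0, anti_aliasing=False,
                  preserve_range=True) > 0.5


def _stack_cohort(cohort, config: ModelConfig):
    size = config.in_size
    xs = np.stack([_resize_image(s.image, size) for s in cohort])[:, None]
    targets = []
    for s in cohort:
        chans = []
        if config.heads in ("lung", "both"):
            chans.append(_resize_mask(s.lung_mask, size))
        if config.heads in ("heart", "both"):
            chans.append(_resize_mask(s.heart_mask, size))
        targets.append(np.stack(chans))
    return xs.astype(np.float32), np.stack(targets).astype(np.float32)


def train(
    model: SegmentationModel,
    cohort: list[SegmentationSample],
    config: TrainConfig,
) -> tuple[SegmentationModel, list[float]]:
    """Train in place; returns the model and the per-epoch mean loss trace.

    Deterministic given ``config.seed`` (pure CPU arithmetic, no threading
    nondeterminism): identical runs give identical traces.
    """
    config.validate()
    if not cohort:
        raise DataError("training cohort is empty")
    xs, ts = _stack_cohort(cohort, model.config)
    n = xs.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb = xs[idx], ts[idx]
            if config.augment and rng.random() < 0.5:
                xb = xb[..., ::-1].copy()
                tb = tb[..., ::-1].copy()
            logits = model.forward(xb)
            loss, dz = _loss_and_grad(logits.astype(np.float64), tb.astype(np.float64))
            opt.zero_grad()
            model.backward(dz.astype(model.dtype))
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def predict_masks(
    model: SegmentationModel,
    image: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Predict binary (lung_mask, heart_mask) at the image's own resolution.

    The image is resampled to the model's input size, probabilities are
    resampled back bilinearly, and thresholded at ``threshold``.  A head the
    model does not carry comes back as ``None``.
    """
    if image.ndim != 2:
        raise ContractError(f"expected a 2-D image, got shape {image.shape}")
    size = model.config.in_size
    x = _resize_image(image, size)[None, None].astype(np.float32)
    probs = expit(model.forward(x).astype(np.float64))[0]
    out_masks = []
    for ch in range(probs.shape[0]):
        pm = probs[ch]
        if image.shape != (size, size):
            pm = resize(pm, image.shape, order=1, anti_aliasing=False, preserve_range=True)
        out_masks.append(pm >= threshold)
    if model.config.heads == "both":
        return out_masks[0], out_masks[1]
    if model.config.heads == "lung":
        return out_masks[0], None
    return None, out_masks[0]


# ---------------------------------------------------------------------------
# Checkpoints: npz of parameter arrays plus a JSON-encoded config.

def save_model(model: SegmentationModel, path: str | Path) -> None:
    arrays = {f"param_{i}": p["value"] for i, p in enumerate(model.params())}
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> SegmentationModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        model = SegmentationModel(config, seed=meta["seed"])
        params = model.params()
        for i, p in enumerate(params):
            arr = data[f"param_{i}"]
            if arr.shape != p["value"].shape:
                raise DataError(
                    f"checkpoint parameter {i} has shape {arr.shape}, "
                    f"architecture expects {p['value'].shape}"
                )
            p["value"][...] = arr
    return model
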