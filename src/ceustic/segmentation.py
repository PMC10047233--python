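"""Per-frame lesion masks for the B-mode panel.

Two interchangeable mask providers implement one contract: given a B-mode
panel raster and a frame index, return a strictly binary 256x256 mask.

* :class:`GroundTruthMaskProvider` serves the phantom generator's truth
  masks (the primary backend for testing the downstream curve extraction).
* :class:`UNetMaskProvider` wraps a small trainable U-Net: a 4-level
  encoder/decoder with 3x3 convolutions, skip connections, nearest-
  neighbour upsampling, sigmoid output and a 0.5 binarisation threshold,
  trained with a Dice + binary-cross-entropy loss.  It is a desk-scale
  network (base 16 channels) validated on synthetic phantoms only.

Panels are resized to 256x256 before inference; callers resize the mask
back to panel size with nearest-neighbour interpolation (preserving
binarity) for any geometry work.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from skimage.transform import resize

from . import _nn
from .frame_io import RegionSpec

__all__ = [
    "MaskProvider",
    "UNetSpec",
    "UNet",
    "GroundTruthMaskProvider",
    "UNetMaskProvider",
    "predict_mask",
    "train_unet",
    "dice_coefficient",
    "resize_mask",
    "panel_to_model",
    "save_unet",
    "load_unet",
]

MODEL_SIZE = 256


class MaskProvider(Protocol):
    """Contract: ``provider(bmode_panel, frame_index) -> (256, 256) bool``."""

    def __call__(self, panel: np.ndarray, frame_index: int) -> np.ndarray: ...


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (binarity preserved)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == tuple(shape):
        return mask
    return resize(mask, shape, order=0, preserve_range=True, anti_aliasing=False) > 0.5


def panel_to_model(panel: np.ndarray) -> np.ndarray:
    """Convert an RGB/gray panel to the model's (256, 256) float32 input in [0, 1]."""
    img = np.asarray(panel, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.max() > 1.0:
        img = img / 255.0
    if img.shape != (MODEL_SIZE, MODEL_SIZE):
        img = resize(img, (MODEL_SIZE, MODEL_SIZE), preserve_range=True,
                     anti_aliasing=True).astype(np.float32)
    return img


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); defined as 1.0 for two empty masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass(frozen=True)
class UNetSpec:
    """Architecture of the desk-scale segmentation network."""

    input_size: int = MODEL_SIZE
    depth: int = 4            # encoder levels incl. the bottleneck
    base_channels: int = 16
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.input_size % 2 ** (self.depth - 1) != 0:
            raise ValueError("input_size must be divisible by 2**(depth-1)")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


class UNet:
    """Encoder/decoder segmentation network on the numpy engine."""

    def __init__(self, spec: UNetSpec = UNetSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = [spec.base_channels * 2**i for i in range(spec.depth)]
        self.enc: list[tuple[_nn.Conv3x3, _nn.Conv3x3]] = []
        c_prev = 1
        for c in ch[:-1]:
            self.enc.append((_nn.Conv3x3(c_prev, c, rng), _nn.Conv3x3(c, c, rng)))
            c_prev = c
        self.bottleneck = (_nn.Conv3x3(c_prev, ch[-1], rng), _nn.Conv3x3(ch[-1], ch[-1], rng))
        self.dec: list[tuple[_nn.Conv3x3, _nn.Conv3x3]] = []
        c_up = ch[-1]
        for c in reversed(ch[:-1]):
            self.dec.append((_nn.Conv3x3(c_up + c, c, rng), _nn.Conv3x3(c, c, rng)))
            c_up = c
        self.head = _nn.Conv1x1(ch[0], 1, rng)
        self.pool = _nn.MaxPool2()
        self.up = _nn.Upsample2()

    def _blocks(self):
        for pair in self.enc:
            yield from pair
        yield from self.bottleneck
        for pair in self.dec:
            yield from pair
        yield self.head

    @property
    def params(self):
        return [p for blk in self._blocks() for p in blk.params]

    @property
    def grads(self):
        return [g for blk in self._blocks() for g in blk.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch ``(n, s, s)`` or ``(n, s, s, 1)`` of inputs."""
        if x.ndim == 3:
            x = x[..., None]
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._pools = []
        self._skips = []
        for conv1, conv2 in self.enc:
            x = conv2.forward(conv1.forward(x))
            self._skips.append(x)
            pool = _nn.MaxPool2()
            self._pools.append(pool)
            x = pool.forward(x)
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x))
        self._ups = []
        self._split = []
        for (conv1, conv2), skip in zip(self.dec, reversed(self._skips)):
            up = _nn.Upsample2()
            self._ups.append(up)
            x = up.forward(x)
            self._split.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            x = conv2.forward(conv1.forward(x))
        return self.head.forward(x)[..., 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[..., None])
        dskips = []
        for (conv1, conv2), up, c_up in zip(
            reversed(self.dec), reversed(self._ups), reversed(self._split)
        ):
            d = conv1.backward(conv2.backward(d))
            dskips.append(d[..., c_up:])
            d = up.backward(np.ascontiguousarray(d[..., :c_up]))
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        for (conv1, conv2), pool, dskip in zip(
            reversed(self.enc), reversed(self._pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            d = conv1.backward(conv2.backward(d))
        self._pools = self._skips = self._ups = self._split = None

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Sigmoid probability map for a single (256, 256) image."""
        logits = self.forward(image[None])
        return _nn.sigmoid(logits[0])


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Dice + BCE loss and its gradient with respect to the logits."""
    p = _nn.sigmoid(logits)
    t = targets.astype(np.float32)
    m = float(p.size)
    eps = 1e-7
    bce = float(-np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
    inter = float((p * t).sum())
    sums = float(p.sum() + t.sum())
    dice = (2.0 * inter + 1.0) / (sums + 1.0)
    loss = bce + (1.0 - dice)
    dbce = (p - t) / m
    ddice_dp = -(2.0 * t * (sums + 1.0) - (2.0 * inter + 1.0)) / (sums + 1.0) ** 2
    dlogits = (dbce + ddice_dp * p * (1 - p)).astype(np.float32)
    return loss, dlogits


class GroundTruthMaskProvider:
    """Serve generator truth masks, cropped to the B-mode panel and resized."""

    def __init__(self, masks: np.ndarray, b_spec: RegionSpec):
        self.masks = np.asarray(masks, dtype=bool)
        self.b_spec = b_spec

    def __call__(self, panel: np.ndarray, frame_index: int) -> np.ndarray:
        full = self.masks[frame_index]
        b = self.b_spec
        panel_mask = full[b.y_min:b.y_max, b.x_min:b.x_max]
        return resize_mask(panel_mask, (MODEL_SIZE, MODEL_SIZE))


class UNetMaskProvider:
    """Binarised U-Net predictions as a mask provider."""

    def __init__(self, model: UNet, threshold: float | None = None):
        self.model = model
        self.threshold = model.spec.threshold if threshold is None else threshold

    def __call__(self, panel: np.ndarray, frame_index: int) -> np.ndarray:
        prob = self.model.predict_proba(panel_to_model(panel))
        return prob >= self.threshold


def predict_mask(provider: MaskProvider, bmode_panel: np.ndarray, frame_index: int) -> np.ndarray:
    """Run a mask provider and validate its output contract."""
    if np.asarray(bmode_panel).size == 0:
        raise ValueError("empty B-mode panel")
    try:
        mask = provider(bmode_panel, frame_index)
    except Exception as exc:
        raise RuntimeError(f"mask provider failed at frame {frame_index}") from exc
    mask = np.asarray(mask)
    if mask.shape != (MODEL_SIZE, MODEL_SIZE):
        raise ValueError(
            f"mask provider returned shape {mask.shape}, expected (256, 256) "
            f"(frame {frame_index})"
        )
    return mask.astype(bool)


def train_unet(
    images: np.ndarray,
    masks: np.ndarray,
    spec: UNetSpec = UNetSpec(),
    epochs: int = 20,
    seed: int = 0,
    batch_size: int = 2,
    learning_rate: float = 1e-3,
    val_fraction: float = 0.2,
    target_val_dice: float | None = None,
    verbose: bool = False,
) -> tuple[UNetMaskProvider, dict]:
    """Train the segmentation network on (image, mask) pairs.

    Images are ``(n, 256, 256)`` floats in [0, 1]; masks are binary of the
    same shape.  A tail fraction of the shuffled data is held out for
    per-epoch validation Dice.  Training stops early once the held-out
    Dice reaches ``target_val_dice`` (if given).  Deterministic for a
    fixed seed.

    Returns the trained provider and a history dict with per-epoch
    ``loss`` and ``val_dice``.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks)
    if images.shape != masks.shape or images.ndim != 3:
        raise ValueError("images and masks must both be (n, s, s) and equal-shaped")
    if not np.isin(np.unique(masks), [0, 1]).all():
        raise ValueError("masks must be binary")
    n = images.shape[0]
    if n < 1:
        raise ValueError("need at least one image/mask pair")
    masks = masks.astype(bool)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(val_fraction * n)) if n >= 2 else 0
    val_idx = order[n - n_val:] if n_val else order[:0]
    train_idx = order[: n - n_val] if n_val else order

    model = UNet(spec, seed=seed)
    opt = _nn.Adam(model.params, lr=learning_rate)
    history: dict[str, list[float]] = {"loss": [], "val_dice": []}

    for epoch in range(epochs):
        perm = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(train_idx), batch_size):
            idx = train_idx[perm[start:start + batch_size]]
            logits = model.forward(images[idx])
            loss, dlogits = dice_bce_loss(logits, masks[idx])
            model.backward(dlogits)
            opt.step(model.grads)
            losses.append(loss)
        provider = UNetMaskProvider(model)
        eval_idx = val_idx if n_val else train_idx
        dices = [
            dice_coefficient(model.predict_proba(images[i]) >= spec.threshold, masks[i])
            for i in eval_idx
        ]
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(float(np.mean(dices)))
        if verbose:
            print(f"epoch {epoch + 1}: loss={history['loss'][-1]:.4f} "
                  f"val_dice={history['val_dice'][-1]:.4f}", flush=True)
        if target_val_dice is not None and history["val_dice"][-1] >= target_val_dice:
            break

    return UNetMaskProvider(model), history


def save_unet(model: UNet, path: str | Path) -> None:
    """Save weights and architecture to an .npz checkpoint."""
    arrays = {f"p{i}": p for i, p in enumerate(model.params)}
    np.savez(
        Path(path),
        _spec=np.array(
            [model.spec.input_size, model.spec.depth, model.spec.base_channels],
            dtype=np.int64,
        ),
        _threshold=np.array([model.spec.threshold]),
        **arrays,
    )


def load_unet(path: str | Path) -> UNet:
    with np.load(Path(path)) as data:
        size, depth, base = (int(v) for v in data["_spec"])
        spec = UNetSpec(size, depth, base, float(data["_threshold"][0]))
        model = UNet(spec)
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
    return model
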