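"""Encoder-decoder segmentation of the endometrium.

The network follows the SegNet pattern with a residual-backbone encoder: a
convolutional stem, four stages of residual blocks, and a 2x2 max-pool after
the stem and after every stage (five halvings in all, hence input sizes must
be divisible by 32).  The decoder mirrors the five poolings with max-unpooling
using the encoder's recorded argmax indices, each followed by one 3x3
convolution, and ends in a single-channel sigmoid head that yields a per-pixel
foreground probability.

Two presets are provided.  ``full`` uses the standard ResNet-50 stage layout
(bottleneck blocks in counts 3/4/6/3, output widths 256/512/1024/2048); the
global average pooling of the classification network is dropped, since a
segmentation encoder must keep its spatial grid.  ``tiny`` keeps the same
topology with basic blocks and small widths, sized so that it trains in
minutes on a CPU — the variant the synthetic-phantom experiments use.

Training minimises binary cross-entropy plus soft Dice loss (their sum by
default), a robust choice for thin, class-imbalanced foregrounds, with the
Adam optimiser.  All arithmetic is NumPy, so runs are reproducible bit for
bit for a fixed seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .datatypes import BinaryMask, Phantom, UltrasoundImage
from .exceptions import ValidationError

__all__ = [
    "SegmentationConfig",
    "TrainingConfig",
    "SegmentationModel",
    "build_model",
    "train",
    "predict",
    "binarize",
    "save_model",
    "load_model",
]

_PRESETS = {
    # stem width, per-stage out widths, blocks per stage, block kind
    "tiny": dict(stem=8, widths=(8, 16, 24, 32), blocks=(1, 1, 1, 1), kind="basic"),
    "full": dict(
        stem=64, widths=(256, 512, 1024, 2048), blocks=(3, 4, 6, 3), kind="bottleneck"
    ),
}

LOSSES = ("bce", "dice", "bce+dice")


@dataclass(frozen=True)
class SegmentationConfig:
    """Architecture parameters of the segmentation network."""

    input_height: int = 128
    input_width: int = 160
    encoder_depth_preset: str = "tiny"
    pretrained_encoder: bool = False
    binarization_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.input_height % 32 or self.input_width % 32:
            raise ValidationError(
                "input_height and input_width must each be divisible by 32 "
                "(five 2x resolution reductions); got "
                f"{self.input_height}x{self.input_width}"
            )
        if self.input_height < 32 or self.input_width < 32:
            raise ValidationError("input size must be at least 32x32")
        if self.encoder_depth_preset not in _PRESETS:
            raise ValidationError(
                f"encoder_depth_preset must be one of {sorted(_PRESETS)}, "
                f"got {self.encoder_depth_preset!r}"
            )
        if self.pretrained_encoder:
            raise ValidationError(
                "pretrained encoder weights are not bundled with this package; "
                "set pretrained_encoder=False"
            )
        if not (0 < self.binarization_threshold < 1):
            raise ValidationError(
                f"binarization_threshold must be in (0, 1), got "
                f"{self.binarization_threshold}"
            )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation parameters for :func:`train`."""

    epochs: int = 20
    batch_size: int = 5
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "bce+dice"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValidationError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if self.loss not in LOSSES:
            raise ValidationError(f"loss must be one of {LOSSES}, got {self.loss!r}")


class SegmentationModel:
    """The encoder-decoder network plus its config and training history."""

    def __init__(self, config: SegmentationConfig, init_seed: int = 0):
        self.config = config
        self.history: list[float] = []
        self._build(init_seed)

    # -- construction ------------------------------------------------------

    def _build(self, init_seed: int) -> None:
        preset = _PRESETS[self.config.encoder_depth_preset]
        rng = np.random.default_rng(init_seed)
        stem_w = preset["stem"]
        widths = preset["widths"]
        kind = preset["kind"]

        self.stem = nn.ConvBNRelu(1, stem_w, 3, rng)
        self.pools = [nn.MaxPool2x2() for _ in range(5)]
        self.stages: list[list[nn.Layer]] = []
        cin = stem_w
        for w, nblocks in zip(widths, preset["blocks"]):
            blocks: list[nn.Layer] = []
            for _ in range(nblocks):
                if kind == "basic":
                    blocks.append(nn.BasicBlock(cin, w, rng))
                else:
                    blocks.append(nn.BottleneckBlock(cin, w // 4, w, rng))
                cin = w
            self.stages.append(blocks)

        # Decoder: five unpool + 3x3-conv stages, deepest first.
        dec_in = (widths[3], widths[2], widths[1], widths[0], stem_w)
        dec_out = (widths[2], widths[1], widths[0], stem_w, stem_w)
        self.decoder = [
            nn.ConvBNRelu(ci, co, 3, rng) for ci, co in zip(dec_in, dec_out)
        ]
        self.head = nn.Conv2d(stem_w, 1, 1, rng)

    def _layers(self) -> list[nn.Layer]:
        layers: list[nn.Layer] = [self.stem]
        for blocks in self.stages:
            layers.extend(blocks)
        layers.extend(self.decoder)
        layers.append(self.head)
        return layers

    def parameters(self) -> list[nn.Param]:
        return [p for layer in self._layers() for p in layer.params()]

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def reinitialize(self, seed: int) -> None:
        """Draw fresh He-normal weights; used by :func:`train` for seeding."""
        self._build(seed)
        self.history = []

    # -- forward / backward ------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on an (N, 1, H, W) batch; returns logits, same shape."""
        self._pool_indices: list[np.ndarray] = []
        y = self.stem.forward(x.astype(np.float32))
        y, idx = self.pools[0].forward(y)
        self._pool_indices.append(idx)
        for s, blocks in enumerate(self.stages):
            for block in blocks:
                y = block.forward(y)
            y, idx = self.pools[s + 1].forward(y)
            self._pool_indices.append(idx)
        self._unpool_indices = list(reversed(self._pool_indices))
        for d, conv in enumerate(self.decoder):
            y = nn.max_unpool_2x2(y, self._unpool_indices[d])
            y = conv.forward(y)
        return self.head.forward(y)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        for d in range(len(self.decoder) - 1, -1, -1):
            g = self.decoder[d].backward(g)
            g = nn.max_unpool_2x2_backward(g, self._unpool_indices[d])
        for s in range(len(self.stages) - 1, -1, -1):
            g = self.pools[s + 1].backward(g)
            for block in reversed(self.stages[s]):
                g = block.backward(g)
        g = self.pools[0].backward(g)
        self.stem.backward(g)

    # -- inference ---------------------------------------------------------

    def predict(self, image: UltrasoundImage | np.ndarray) -> np.ndarray:
        """Per-pixel foreground probability map, same shape as the input.

        Inputs whose height/width are not multiples of 32 are symmetrically
        zero-padded up to the next multiple and the output is cropped back,
        so the pixel grid is preserved for downstream geometry.
        """
        px = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D image, got shape {px.shape}")
        h, w = px.shape
        if h < 2 or w < 2:
            raise ValidationError(
                f"image {h}x{w} is smaller than one downsampling step"
            )
        ph = (32 - h % 32) % 32
        pw = (32 - w % 32) % 32
        top, left = ph // 2, pw // 2
        padded = np.pad(px, ((top, ph - top), (left, pw - left)))
        logits = self.forward_logits(padded[None, None].astype(np.float32))
        probs = _sigmoid(logits[0, 0])
        return probs[top : top + h, left : left + w].astype(float)

    def segment(self, image: UltrasoundImage | np.ndarray) -> BinaryMask:
        """Predict and binarise at the configured threshold."""
        return binarize(self.predict(image), self.config.binarization_threshold)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_model(config: SegmentationConfig, init_seed: int = 0) -> SegmentationModel:
    """Construct an untrained network for the given configuration."""
    return SegmentationModel(config, init_seed=init_seed)


def _fit_to_shape(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    """Centre-pad with zeros and/or centre-crop to (h, w)."""
    ah, aw = arr.shape
    ph, pw = max(0, h - ah), max(0, w - aw)
    if ph or pw:
        arr = np.pad(arr, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))
    ah, aw = arr.shape
    oh, ow = (ah - h) // 2, (aw - w) // 2
    return arr[oh : oh + h, ow : ow + w]


def _loss_and_grad(
    logits: np.ndarray, y: np.ndarray, loss: str
) -> tuple[float, np.ndarray]:
    """Mean loss over the batch and its gradient w.r.t. the logits."""
    p = _sigmoid(logits)
    npix = logits.size
    eps = 1e-7
    value = 0.0
    grad = np.zeros_like(p)
    if loss in ("bce", "bce+dice"):
        value += float(
            -(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)).mean()
        )
        grad += (p - y) / npix
    if loss in ("dice", "bce+dice"):
        a = float((p * y).sum())
        b = float(p.sum() + y.sum())
        dice = (2.0 * a + 1.0) / (b + 1.0)
        value += 1.0 - dice
        ddice_dp = (2.0 * y * (b + 1.0) - (2.0 * a + 1.0)) / (b + 1.0) ** 2
        grad += -ddice_dp * p * (1.0 - p)
    return value, grad.astype(np.float32)


def train(
    model: SegmentationModel,
    phantoms: list[Phantom],
    tconfig: TrainingConfig,
) -> SegmentationModel:
    """Train the model in place on a phantom cohort; returns the model.

    Weights are freshly initialised from ``tconfig.seed`` so the pair
    (phantom list, training config) fully determines the run.  Images are
    centre-padded/cropped to the configured input size by the loader.  One
    entry of mean minibatch loss is appended to ``model.history`` per epoch.
    """
    if not phantoms:
        raise ValidationError("training requires at least one phantom")
    h, w = model.config.input_height, model.config.input_width
    x = np.stack(
        [_fit_to_shape(p.image.pixels, h, w) for p in phantoms]
    )[:, None].astype(np.float32)
    y = np.stack(
        [_fit_to_shape(p.mask.values.astype(np.float32), h, w) for p in phantoms]
    )[:, None]

    model.reinitialize(tconfig.seed)
    rng = np.random.default_rng(tconfig.seed)
    opt = nn.Adam(model.parameters(), lr=tconfig.learning_rate)

    n = len(phantoms)
    for _epoch in range(tconfig.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tconfig.batch_size):
            batch = order[start : start + tconfig.batch_size]
            logits = model.forward_logits(x[batch])
            value, grad = _loss_and_grad(logits, y[batch], tconfig.loss)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(value)
        model.history.append(float(np.mean(losses)))
    return model


def predict(model: SegmentationModel, image: UltrasoundImage | np.ndarray) -> np.ndarray:
    """Functional wrapper around :meth:`SegmentationModel.predict`."""
    return model.predict(image)


def binarize(prob_map: np.ndarray, threshold: float) -> BinaryMask:
    """Threshold a probability map; foreground is strictly above threshold."""
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValidationError("probability map values must lie in [0, 1]")
    return BinaryMask(prob_map > threshold)


# -- checkpointing ---------------------------------------------------------


def save_model(model: SegmentationModel, path) -> None:
    """Write a single-file checkpoint: config JSON plus all weight arrays."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    meta = json.dumps(
        {"config": asdict(model.config), "history": model.history}
    )
    with open(path, "wb") as fh:
        np.savez(fh, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> SegmentationModel:
    """Reconstruct a model (architecture + weights + history) from disk."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = SegmentationModel(SegmentationConfig(**meta["config"]))
        params = model.parameters()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValidationError("checkpoint does not match the architecture")
            p.value[...] = stored
    model.history = list(meta["history"])
    return model
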