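"""Network architectures for localization classification.

Both classifiers share one convolutional trunk: repeated blocks of two
3x3 convolutions (ReLU after each), batch normalization, and 2x2 max
pooling, with the kernel count doubling after every pooling stage and
ten convolutional layers in total at the default depth.

* The CNN appends flatten + three fully connected layers; the last layer
  has 13 outputs, one sigmoid confidence per organelle class.
* The FCN drops the final max-pooling stage and appends a single 3x3
  convolution with 13 kernels + sigmoid, producing one heatmap per class
  (16x16 for 256x256 input).  Its per-class confidence is the heatmap
  maximum.

All weights are Glorot-initialized from a seeded generator, so model
construction is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .classes import N_CLASSES

__all__ = [
    "NetworkSpec",
    "PredictionRecord",
    "Model",
    "build_base_trunk",
    "build_cnn",
    "build_fcn",
    "predict",
    "resize_nearest",
    "count_conv_layers",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    """Architecture hyperparameters shared by the CNN and FCN variants."""

    input_side: int = 256
    in_channels: int = 4
    convs_per_block: int = 2
    base_kernels: int = 16
    kernel_size: int = 3
    pool_blocks: int = 5
    variant: str = "CNN"
    n_classes: int = N_CLASSES
    fc_widths: tuple[int, int, int] = (256, 128, N_CLASSES)
    dropout_rate: float = 0.2
    seed: int = 0

    @property
    def conv_layers_total(self) -> int:
        """Trunk conv layers: convs_per_block per pooling block."""
        return self.convs_per_block * self.pool_blocks

    def validate(self) -> None:
        if self.variant not in ("CNN", "FCN"):
            raise ValueError(f"variant must be CNN or FCN, got {self.variant!r}")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.input_side % (2**self.pool_blocks) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by 2^{self.pool_blocks}"
            )
        if self.variant == "FCN" and self.input_side < 2 ** (self.pool_blocks - 1):
            raise ValueError("input too small for the FCN pooling stages")
        if self.fc_widths[-1] != self.n_classes:
            raise ValueError("last fully connected width must equal n_classes")

    @property
    def fcn_out_side(self) -> int:
        """Heatmap side length: one pooling stage fewer than the trunk."""
        return self.input_side // 2 ** (self.pool_blocks - 1)


@dataclass
class PredictionRecord:
    """Per-sample prediction: 13 confidences, plus heatmaps for the FCN."""

    sample_id: str
    confidences: np.ndarray
    heatmaps: np.ndarray | None = None


def build_base_trunk(spec: NetworkSpec, rng: np.random.Generator) -> list[nn.Layer]:
    """Pooling blocks of [conv, relu] * convs_per_block + batchnorm + maxpool."""
    layers: list[nn.Layer] = []
    in_ch = spec.in_channels
    width = spec.base_kernels
    for _ in range(spec.pool_blocks):
        for _ in range(spec.convs_per_block):
            layers.append(nn.Conv2d(in_ch, width, spec.kernel_size, rng))
            layers.append(nn.ReLU())
            in_ch = width
        layers.append(nn.BatchNorm2d(width))
        layers.append(nn.MaxPool2d())
        width *= 2
    return layers


@dataclass
class Model:
    spec: NetworkSpec
    net: nn.Sequential

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def params(self) -> list[nn.Param]:
        return self.net.params()


def build_cnn(spec: NetworkSpec) -> Model:
    spec.variant = "CNN"
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    layers = build_base_trunk(spec, rng)
    side = spec.input_side // 2**spec.pool_blocks
    feat = spec.base_kernels * 2 ** (spec.pool_blocks - 1) * side * side
    layers.append(nn.Flatten())
    widths = list(spec.fc_widths)
    in_dim = feat
    for i, w in enumerate(widths):
        layers.append(nn.Dense(in_dim, w, rng))
        if i < len(widths) - 1:
            layers.append(nn.ReLU())
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        in_dim = w
    layers.append(nn.Sigmoid())
    return Model(spec, nn.Sequential(layers))


def build_fcn(spec: NetworkSpec) -> Model:
    spec.variant = "FCN"
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    layers = build_base_trunk(spec, rng)
    # remove the final max pooling stage to double the output resolution
    last_pool = max(i for i, l in enumerate(layers) if isinstance(l, nn.MaxPool2d))
    del layers[last_pool]
    width = spec.base_kernels * 2 ** (spec.pool_blocks - 1)
    layers.append(nn.Dropout(spec.dropout_rate, rng))
    layers.append(nn.Conv2d(width, spec.n_classes, spec.kernel_size, rng))
    layers.append(nn.Sigmoid())
    return Model(spec, nn.Sequential(layers))


def build_model(spec: NetworkSpec) -> Model:
    return build_cnn(spec) if spec.variant == "CNN" else build_fcn(spec)


def count_conv_layers(model: Model, include_head: bool = False) -> int:
    """Number of convolutional layers; the FCN prediction conv is a head layer."""
    convs = [l for l in model.net if isinstance(l, nn.Conv2d)]
    if not include_head and model.spec.variant == "FCN":
        return len(convs) - 1
    return len(convs)


def count_parameters(model: Model) -> int:
    return sum(p.value.size for p in model.params())


def resize_nearest(image: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour resize of a (C, H, W) image to (C, side, side)."""
    c, h, w = image.shape
    rows = np.floor((np.arange(side) + 0.5) * h / side).astype(int)
    cols = np.floor((np.arange(side) + 0.5) * w / side).astype(int)
    return image[:, rows[:, None], cols[None, :]]


def predict(model: Model, image: np.ndarray, sample_id: str = "") -> PredictionRecord:
    """Run one 4-channel image through the model.

    The image is resized to ``spec.input_side`` with nearest-neighbour
    resampling.  CNN confidences are the direct sigmoid outputs; FCN
    confidences are the per-class heatmap maxima.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != model.spec.in_channels:
        raise ValueError(
            f"expected ({model.spec.in_channels}, H, W) image, got shape {image.shape}"
        )
    if image.shape[1:] != (model.spec.input_side,) * 2:
        image = resize_nearest(image, model.spec.input_side)
    out = model.forward(image[None], train=False)[0]
    if model.spec.variant == "FCN":
        return PredictionRecord(sample_id, out.max(axis=(1, 2)), heatmaps=out)
    return PredictionRecord(sample_id, out)


def predict_batch(model: Model, images: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Confidence matrix (n, 13) for pre-sized (n, C, S, S) images (chunked)."""
    images = np.asarray(images, dtype=float)
    rows = []
    for i in range(0, len(images), chunk):
        out = model.forward(images[i : i + chunk], train=False)
        rows.append(out.max(axis=(2, 3)) if model.spec.variant == "FCN" else out)
    return np.concatenate(rows, axis=0)


def _bn_state(model: Model) -> dict[str, np.ndarray]:
    state = {}
    for i, layer in enumerate(model.net):
        if isinstance(layer, nn.BatchNorm2d):
            for k, v in layer.state().items():
                state[f"bn{i}_{k}"] = v
    return state


def save_checkpoint(model: Model, path: str | Path) -> None:
    """Write weights as .npz plus a JSON sidecar recording the NetworkSpec."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays.update(_bn_state(model))
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(asdict(model.spec), indent=2))


def load_checkpoint(path: str | Path) -> Model:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["fc_widths"] = tuple(cfg["fc_widths"])
    spec = NetworkSpec(**cfg)
    model = build_model(spec)
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    for i, layer in enumerate(model.net):
        if isinstance(layer, nn.BatchNorm2d):
            layer.running_mean = data[f"bn{i}_running_mean"]
            layer.running_var = data[f"bn{i}_running_var"]
    return model
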