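"""Synthetic image fixtures and desk-scale CNNs.

Everything here exists so the activation catalogue, network surgery,
training loop and ensemble machinery can be exercised end to end on one
CPU with no external data:

* ``gen_classification`` — classes are sinusoidal textures at
  class-specific spatial frequencies (random orientation and phase per
  image) plus Gaussian noise.  With zero noise the classes are perfectly
  separable from the radial power spectrum alone, which gives tests a
  closed-form oracle.
* ``gen_segmentation`` — random ellipses filled with a foreground
  ("skin-like") color cluster on a background-cluster canvas, with exact
  ground-truth masks by construction.
* ``tiny_cnn`` / ``tiny_segmenter`` — small conv stacks with a chosen
  number of named activation slots, trainable in seconds.
* ``desk_benchmark`` — the full comparison (single all-ReLU model vs a
  stochastic-replacement ensemble fused by the sum rule) at toy scale.

These fixtures emulate the two task *types* (texture-like image
classification, color-cluster segmentation), not the statistics of any
real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage.draw import ellipse as _ellipse

from .ensembling import create_ensemble
from .model import (
    ActivationLayer,
    AvgPool2D,
    Conv2D,
    Dense,
    Flatten,
    InputCenter,
    ModelGraph,
    Softmax,
    Upsample2D,
)
from .activations import ActivationSpec
from .surgery import default_pool
from .train_eval import TrainConfig, accuracy, train

__all__ = [
    "SynthClassSpec",
    "SynthSegSpec",
    "gen_classification",
    "gen_segmentation",
    "tiny_cnn",
    "tiny_segmenter",
    "desk_benchmark",
]


@dataclass(frozen=True)
class SynthClassSpec:
    """Texture-classification fixture parameters.

    ``texture_freqs`` (cycles per image width, one per class) defaults to
    3, 6, 9, ... — well separated so the noise-free task is exactly
    separable in the frequency domain.  ``noise_sd`` is the per-pixel
    Gaussian noise level on a [0, 1] intensity scale.
    """

    n_classes: int = 3
    n_per_class: int = 20
    image_size: Tuple[int, int, int] = (32, 32, 3)
    texture_freqs: Optional[Tuple[float, ...]] = None
    noise_sd: float = 0.2
    seed: int = 0

    def freqs(self) -> Tuple[float, ...]:
        if self.texture_freqs is not None:
            if len(self.texture_freqs) != self.n_classes:
                raise ValueError("need one texture frequency per class")
            return tuple(self.texture_freqs)
        return tuple(3.0 * (i + 1) for i in range(self.n_classes))


@dataclass(frozen=True)
class SynthSegSpec:
    """Ellipse-segmentation fixture parameters.

    Foreground pixels are drawn from a skin-like RGB cluster, background
    from a cooler cluster; ``min_axis``/``max_axis`` bound the ellipse
    semi-axes as fractions of the image side.
    """

    n_images: int = 20
    image_size: Tuple[int, int, int] = (32, 32, 3)
    fg_color_mean: Tuple[float, float, float] = (0.80, 0.60, 0.50)
    fg_color_sd: Tuple[float, float, float] = (0.05, 0.05, 0.05)
    bg_color_mean: Tuple[float, float, float] = (0.35, 0.45, 0.55)
    bg_color_sd: Tuple[float, float, float] = (0.08, 0.08, 0.08)
    min_axis: float = 0.15
    max_axis: float = 0.35
    seed: int = 0


def gen_classification(spec: SynthClassSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Generate (images, labels): images (N, H, W, C) in [0, 1], labels (N,).

    Class ``c`` images contain a sinusoidal grating at spatial frequency
    ``freqs[c]`` with a random orientation and phase, identical across
    color channels, plus i.i.d. Gaussian noise.  Deterministic under
    ``spec.seed``; samples are ordered class-by-class.
    """
    if spec.n_classes < 2:
        raise ValueError("need at least 2 classes")
    h, w, ch = spec.image_size
    if h < 2 or w < 2 or ch < 1:
        raise ValueError(f"invalid image size {spec.image_size}")
    rng = np.random.default_rng(spec.seed)
    freqs = spec.freqs()
    vv, uu = np.meshgrid(np.linspace(0, 1, h, endpoint=False),
                         np.linspace(0, 1, w, endpoint=False), indexing="ij")
    images, labels = [], []
    for c in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            theta = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            pattern = np.sin(
                2 * np.pi * freqs[c] * (uu * np.cos(theta) + vv * np.sin(theta)) + phase
            )
            img = 0.5 + 0.35 * pattern
            img = np.repeat(img[:, :, None], ch, axis=2)
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(c)
    return np.stack(images), np.asarray(labels)


def gen_segmentation(spec: SynthSegSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Generate (images, masks): images (N, H, W, 3), binary masks (N, H, W).

    One random ellipse per image, painted with per-pixel samples from the
    foreground color cluster over a background-cluster canvas.  The mask
    marks exactly the painted pixels.
    """
    if spec.n_images < 1:
        raise ValueError("need at least one image")
    h, w, ch = spec.image_size
    if spec.max_axis >= 0.5:
        raise ValueError("ellipse axes must fit inside the canvas")
    rng = np.random.default_rng(spec.seed)
    fg_m = np.asarray(spec.fg_color_mean)
    fg_s = np.asarray(spec.fg_color_sd)
    bg_m = np.asarray(spec.bg_color_mean)
    bg_s = np.asarray(spec.bg_color_sd)
    images, masks = [], []
    for _ in range(spec.n_images):
        img = bg_m + bg_s * rng.standard_normal((h, w, ch))
        ry = rng.uniform(spec.min_axis, spec.max_axis) * h
        rx = rng.uniform(spec.min_axis, spec.max_axis) * w
        cy = rng.uniform(ry, h - 1 - ry)
        cx = rng.uniform(rx, w - 1 - rx)
        rot = rng.uniform(0, np.pi)
        rr, cc = _ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        img[rr, cc] = fg_m + fg_s * rng.standard_normal((rr.size, ch))
        mask = np.zeros((h, w), dtype=int)
        mask[rr, cc] = 1
        images.append(np.clip(img, 0.0, 1.0))
        masks.append(mask)
    return np.stack(images), np.stack(masks)


def _relu_layer(channels):
    return ActivationLayer(ActivationSpec.create("ReLU"), channels)


def tiny_cnn(
    n_classes: int,
    n_act_layers: int = 3,
    seed: int = 0,
    image_size: Tuple[int, int, int] = (32, 32, 3),
    width: int = 8,
) -> ModelGraph:
    """A small conv–ReLU–pool classifier with ``n_act_layers`` slots.

    Each block is a same-padded 3x3 convolution of ``width`` channels
    followed by an activation slot; the first two blocks also halve the
    resolution with 2x2 average pooling.  Ends in flatten, dense and
    softmax.  Deterministic initial weights under ``seed``.
    """
    if n_act_layers < 1:
        raise ValueError("need at least one activation layer")
    h, w, ch = image_size
    rng = np.random.default_rng(seed)
    layers = [InputCenter(0.5)]
    c_in = ch
    res_h, res_w = h, w
    for i in range(n_act_layers):
        layers.append(Conv2D.init(c_in, width, 3, rng))
        layers.append(_relu_layer(width))
        if i < 2 and res_h % 2 == 0 and res_w % 2 == 0 and min(res_h, res_w) > 4:
            layers.append(AvgPool2D())
            res_h //= 2
            res_w //= 2
        c_in = width
    layers.append(Flatten())
    layers.append(Dense.init(c_in * res_h * res_w, n_classes, rng))
    layers.append(Softmax())
    return ModelGraph(layers, image_size)


def tiny_segmenter(
    n_classes: int = 2,
    seed: int = 0,
    image_size: Tuple[int, int, int] = (32, 32, 3),
    width: int = 8,
) -> ModelGraph:
    """A mirrored encoder–decoder with per-pixel softmax (2 slots).

    conv–act–pool / conv–act–upsample / 1x1 conv to class scores; outputs
    (N, K, H, W) per-pixel probabilities.
    """
    h, w, ch = image_size
    rng = np.random.default_rng(seed)
    layers = [
        InputCenter(0.5),
        Conv2D.init(ch, width, 3, rng),
        _relu_layer(width),
        AvgPool2D(),
        Conv2D.init(width, width, 3, rng),
        _relu_layer(width),
        Upsample2D(),
        Conv2D.init(width, n_classes, 1, rng),
        Softmax(),
    ]
    return ModelGraph(layers, image_size)


# ---------------------------------------------------------------------------
# desk-scale benchmark


@dataclass
class BenchmarkResult:
    """Accuracies of the single all-ReLU model and the stochastic ensemble."""

    relu_accuracy: float
    ensemble_accuracy: float
    member_accuracies: List[float] = field(default_factory=list)


def _split(labels, frac, rng):
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        cut = int(round(frac * len(idx)))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    return np.asarray(train_idx), np.asarray(test_idx)


def desk_benchmark(
    seed: int = 0,
    n_classes: int = 3,
    n_per_class: int = 20,
    noise_sd: float = 0.2,
    ensemble_size: int = 5,
    epochs: int = 8,
    max_input: float = 1.0,
) -> BenchmarkResult:
    """Single all-ReLU CNN vs a stochastic-replacement sum-rule ensemble.

    Generates the 3-class texture task, splits it 2:1 into train and test
    (stratified), trains one all-ReLU tiny CNN and ``ensemble_size``
    stochastic replacements of it from the same initial weights, and
    reports test accuracies.  Training runs from scratch, so it uses a
    larger step size than the fine-tuning default (SGD with momentum,
    learning rate 0.05, batch size 8) and no augmentation — the rescale
    augmentation would corrupt the frequency coding that defines the
    synthetic classes.
    """
    data_spec = SynthClassSpec(n_classes=n_classes, n_per_class=n_per_class,
                               noise_sd=noise_sd, seed=seed)
    images, labels = gen_classification(data_spec)
    rng = np.random.default_rng(seed + 1)
    tr, te = _split(labels, 2.0 / 3.0, rng)

    cfg = TrainConfig(batch_size=8, learning_rate=0.05, max_epochs=epochs,
                      augmentation=False)
    base = tiny_cnn(n_classes, n_act_layers=3, seed=seed)

    relu_model = train(base, images[tr], labels[tr], cfg, seed=seed + 2)
    x_te = np.transpose(images[te], (0, 3, 1, 2))
    relu_acc = accuracy(np.argmax(relu_model.predict_proba(x_te), axis=1), labels[te])

    def trainer(model, member_seed):
        return train(model, images[tr], labels[tr], cfg, seed=member_seed)

    ens = create_ensemble(base, default_pool(max_input), n=ensemble_size,
                          seed=seed + 3, trainer=trainer)
    member_accs = [
        accuracy(np.argmax(m.predict_proba(x_te), axis=1), labels[te])
        for m in ens.members
    ]
    ens_acc = accuracy(ens.predict(x_te), labels[te])
    return BenchmarkResult(relu_acc, ens_acc, member_accs)
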