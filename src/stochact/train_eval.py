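"""Training contract, augmentation, and evaluation statistics.

Training uses minibatch SGD with momentum on a (pixel-wise, optionally
class-weighted) cross-entropy loss, with the standard fine-tuning settings
as defaults: batch size 32, learning rate 1e-4 for classification and 1e-3
for segmentation, 30/50 max epochs, and an augmentation recipe of random
reflections on both axes plus two independent random axis rescales with
factors drawn uniformly from [1, 2].

Evaluation statistics are the ones conventional for these two tasks:
classification accuracy, pixel-level F1 (2tp / (2tp + fn + fp), aggregated
over all pixels of a dataset rather than averaged per image), and the
two-sided Wilcoxon signed-rank test for paired method comparisons across
datasets — computed by exact enumeration of sign assignments for small n,
where the normal approximation is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import KFold, StratifiedKFold

from .model import ActivationLayer, ModelGraph

__all__ = [
    "TrainConfig",
    "augment",
    "augment_pair",
    "train",
    "accuracy",
    "pixel_f1",
    "wilcoxon_signed_rank",
    "resize_for_model",
    "resize_mask_back",
    "kfold_indices",
    "EvalReport",
    "evaluation_report",
    "pairwise_wilcoxon",
]


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters (defaults = the standard recipe)."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 30
    augmentation: bool = True
    augment_epochs: Optional[int] = None   # None = all epochs
    class_weighting: bool = False
    input_size: Tuple[int, int] = (224, 224)
    momentum: float = 0.9
    grad_clip: Optional[float] = 5.0   # per-tensor L2 norm cap; None disables

    @classmethod
    def classification(cls, **over) -> "TrainConfig":
        return replace(cls(), **over)

    @classmethod
    def segmentation(cls, **over) -> "TrainConfig":
        base = cls(learning_rate=1e-3, max_epochs=50, augment_epochs=30,
                   class_weighting=True)
        return replace(base, **over)


# ---------------------------------------------------------------------------
# augmentation


def _resize(img, shape, order):
    return _sk_resize(img, shape, order=order, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def _augment_params(shape, rng):
    h, w = shape[:2]
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    sy, sx = rng.uniform(1.0, 2.0, size=2)
    return flip_h, flip_v, sy, sx


def _apply_augment(img, params, order):
    flip_h, flip_v, sy, sx = params
    h, w = img.shape[:2]
    out = img
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    nh, nw = max(h, int(round(h * sy))), max(w, int(round(w * sx)))
    if (nh, nw) != (h, w):
        out = _resize(out, (nh, nw) + out.shape[2:], order=order)
        top, left = (nh - h) // 2, (nw - w) // 2
        out = out[top : top + h, left : left + w]
    return np.ascontiguousarray(out)


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random reflections on both axes plus independent axis rescales.

    Each axis flips with probability 1/2; then the two axes are rescaled by
    independent factors ~ Uniform(1, 2) (bilinear) and the result is
    center-cropped back to the original shape.  Deterministic given ``rng``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot augment an empty image")
    return _apply_augment(image, _augment_params(image.shape, rng), order=1)


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Augment an image and its label mask with the same random draws.

    The mask uses nearest-neighbor interpolation so labels stay integral
    and pixel-aligned with the image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot augment an empty image")
    params = _augment_params(image.shape, rng)
    img_out = _apply_augment(image, params, order=1)
    mask_out = _apply_augment(np.asarray(mask, dtype=np.float64), params, order=0)
    return img_out, np.rint(mask_out).astype(int)


# ---------------------------------------------------------------------------
# training


def _nchw(images):
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4:
        raise ValueError("images must be (N, H, W, C)")
    return np.transpose(images, (0, 3, 1, 2))


def _class_weights(labels, n_classes):
    counts = np.bincount(labels.reshape(-1), minlength=n_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / (n_classes * counts)   # inverse-frequency, mean ~ 1
    return w


def train(
    model: ModelGraph,
    images: np.ndarray,
    labels: np.ndarray,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> ModelGraph:
    """Fine-tune ``model`` on labeled data; returns a trained copy.

    ``images`` is (N, H, W, C) float; ``labels`` is (N,) integer class
    labels for classification or (N, H, W) integer masks for segmentation
    (detected by shape).  The loss is cross-entropy on the softmax output,
    pixel-wise and optionally inverse-frequency class-weighted for
    segmentation, plus the APLU hinge-slope L2 penalty where present.
    Optimization is SGD with momentum; a fixed seed makes the run
    bit-reproducible.  The returned model carries the per-epoch mean loss
    in ``loss_history``.
    """
    if config is None:
        config = TrainConfig()
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("training set is empty")
    if labels.shape[0] != images.shape[0]:
        raise ValueError("images and labels disagree on sample count")
    segmentation = labels.ndim == 3

    x_all = _nchw(images)
    probe = model.predict_proba(x_all[:1])
    n_classes = probe.shape[1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"labels must lie in [0, {n_classes}); got range "
            f"[{labels.min()}, {labels.max()}]"
        )

    out = model.copy()
    out.loss_history = []
    if config.max_epochs <= 0:
        return out
    if out.layers[-1].kind != "softmax":
        raise ValueError("training expects a softmax output layer")

    weights = None
    if segmentation and config.class_weighting:
        weights = _class_weights(labels, n_classes)

    rng = np.random.default_rng(seed)
    velocity: Dict[Tuple[int, str], np.ndarray] = {}
    n = images.shape[0]
    aug_epochs = config.augment_epochs if config.augment_epochs is not None else config.max_epochs

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        do_aug = config.augmentation and epoch < aug_epochs
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if do_aug:
                xb_list, yb_list = [], []
                for i in idx:
                    if segmentation:
                        im, mk = augment_pair(images[i], labels[i], rng)
                        xb_list.append(im)
                        yb_list.append(mk)
                    else:
                        xb_list.append(augment(images[i], rng))
                        yb_list.append(labels[i])
                xb = _nchw(np.stack(xb_list))
                yb = np.stack(yb_list) if segmentation else np.asarray(yb_list)
            else:
                xb = x_all[idx]
                yb = labels[idx]

            probs = out.forward(xb, train=True)
            eps = 1e-12
            if segmentation:
                onehot = np.moveaxis(np.eye(n_classes)[yb], -1, 1)  # (N, K, H, W)
                w_pix = weights[yb][:, None] if weights is not None else 1.0
                norm = float(np.sum(w_pix * np.ones_like(probs[:, :1]))) or 1.0
                loss = -np.sum(w_pix * onehot * np.log(probs + eps)) / norm
                grad = w_pix * (probs - onehot) / norm
            else:
                onehot = np.eye(n_classes)[yb]
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
                grad = (probs - onehot) / len(yb)

            # fused softmax + cross-entropy gradient: skip the softmax layer
            g = grad
            for layer in reversed(out.layers[:-1]):
                g = layer.backward(g)

            for li, layer in enumerate(out.layers):
                grads = layer.grads()
                if not grads:
                    continue
                if layer.kind == "activation":
                    loss += layer.penalty()
                    for pname, pg in layer.penalty_grads().items():
                        grads[pname] = grads[pname] + pg
                params = layer.params()
                for pname, g_arr in grads.items():
                    if config.grad_clip is not None:
                        norm = float(np.linalg.norm(g_arr))
                        if norm > config.grad_clip:
                            g_arr = g_arr * (config.grad_clip / norm)
                    key = (li, pname)
                    v = velocity.get(key)
                    if v is None:
                        v = np.zeros_like(g_arr)
                    v = config.momentum * v + g_arr
                    velocity[key] = v
                    params[pname] -= config.learning_rate * v
            epoch_loss += float(loss)
            n_batches += 1
        out.loss_history.append(epoch_loss / max(n_batches, 1))
    return out


# ---------------------------------------------------------------------------
# metrics


def accuracy(decisions: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correct predictions."""
    decisions = np.asarray(decisions)
    truth = np.asarray(truth)
    if decisions.shape != truth.shape:
        raise ValueError("decisions and truth must have the same shape")
    if decisions.size == 0:
        raise ValueError("cannot score empty label vectors")
    return float(np.mean(decisions == truth))


def pixel_f1(pred_mask, gt_mask) -> float:
    """Pixel-level F1 = 2tp / (2tp + fn + fp), aggregated over all pixels.

    Accepts single binary masks or sequences of masks (one per image);
    counts are pooled across the whole collection before the ratio is
    taken.  An empty-truth, empty-prediction dataset scores 1.0.
    """
    preds = pred_mask if isinstance(pred_mask, (list, tuple)) else [pred_mask]
    gts = gt_mask if isinstance(gt_mask, (list, tuple)) else [gt_mask]
    if len(preds) != len(gts):
        raise ValueError("prediction and truth collections differ in length")
    tp = fp = fn = 0
    for p, g in zip(preds, gts):
        p = np.asarray(p).astype(bool)
        g = np.asarray(g).astype(bool)
        if p.shape != g.shape:
            raise ValueError(f"mask shape mismatch: {p.shape} vs {g.shape}")
        tp += int(np.sum(p & g))
        fp += int(np.sum(p & ~g))
        fn += int(np.sum(~p & g))
    if tp == fp == fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fn + fp)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float],
                         exact_n: int = 12) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; tied absolute differences receive
    midranks.  For up to ``exact_n`` nonzero differences the null
    distribution of the positive-rank sum is enumerated over all 2^n sign
    assignments (valid under ties, unlike the textbook tables); larger
    samples fall back to the normal approximation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))
    total = float(np.sum(ranks))
    n = d.size
    if n <= exact_n:
        subsets = np.arange(2 ** n, dtype=np.uint64)
        bits = (subsets[:, None] >> np.arange(n, dtype=np.uint64)) & 1
        dist = bits.astype(np.float64) @ ranks
        lo, hi = min(w_pos, total - w_pos), max(w_pos, total - w_pos)
        tol = 1e-9
        p = (np.sum(dist <= lo + tol) + np.sum(dist >= hi - tol)) / dist.size
        return float(min(p, 1.0))
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# resizing conventions


def resize_for_model(image: np.ndarray, size: Tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bilinear resize to the network input size (identity if already there)."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0 or size[0] <= 0 or size[1] <= 0:
        raise ValueError("empty image or zero-sized target")
    if image.shape[:2] == tuple(size):
        return image
    return _resize(image, tuple(size) + image.shape[2:], order=1)


def resize_mask_back(mask: np.ndarray, original_size: Tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize of an integer label mask to its source size."""
    mask = np.asarray(mask)
    if mask.size == 0 or original_size[0] <= 0 or original_size[1] <= 0:
        raise ValueError("empty mask or zero-sized target")
    if mask.shape[:2] == tuple(original_size):
        return mask
    out = _resize(mask.astype(np.float64), tuple(original_size), order=0)
    return np.rint(out).astype(mask.dtype)


def kfold_indices(labels: np.ndarray, k: int = 5, seed: int = 0,
                  stratified: bool = True) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs for k-fold cross-validation."""
    labels = np.asarray(labels)
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(labels)), labels))


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvalReport:
    """Per-dataset metrics with averages, ranks, and pairwise p-values."""

    table: pd.DataFrame        # methods x (datasets..., Avg, Rank)
    pairwise_p: pd.DataFrame   # methods x methods Wilcoxon p-values

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.4f")


def evaluation_report(scores: Dict[str, Dict[str, float]]) -> pd.DataFrame:
    """Build a methods-by-datasets table with Avg and Rank columns.

    ``scores[method][dataset]`` is a metric in [0, 1] (or percent); Rank
    is 1 for the best average, ties sharing the smaller rank.
    """
    df = pd.DataFrame(scores).T
    df["Avg"] = df.mean(axis=1)
    df["Rank"] = df["Avg"].rank(ascending=False, method="min").astype(int)
    return df


def pairwise_wilcoxon(scores: Dict[str, Dict[str, float]]) -> pd.DataFrame:
    """Wilcoxon signed-rank p-values for every pair of methods."""
    methods = list(scores)
    datasets = list(next(iter(scores.values())))
    mat = pd.DataFrame(np.ones((len(methods), len(methods))),
                       index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for mj in methods[i + 1 :]:
            ai = [scores[mi][d] for d in datasets]
            aj = [scores[mj][d] for d in datasets]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = wilcoxon_signed_rank(ai, aj)
            mat.loc[mi, mj] = mat.loc[mj, mi] = p
    return mat


def full_report(scores: Dict[str, Dict[str, float]]) -> EvalReport:
    return EvalReport(evaluation_report(scores), pairwise_wilcoxon(scores))
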