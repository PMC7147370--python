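"""A small CNN container with explicit forward/backward passes.

``ModelGraph`` is an ordered stack of layers (convolution, activation,
average pooling, upsampling, flatten, dense, softmax) over ``(N, C, H, W)``
float tensors.  Backpropagation is written out explicitly so that the
activation layers can expose analytic gradients for their learnable
parameters (PReLU slopes, SReLU knots, APLU hinges, MeLU/GaLU
coefficients) alongside the usual weight gradients.

The container doubles as the unit of "network surgery": activation layers
are first-class, enumerable slots that can be swapped without touching any
other layer's weights.  Networks serialize to plain JSON (weights as nested
lists), which keeps models diffable and round-trips bit-exactly for
float64 storage.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Optional, Sequence

import numpy as np

from .activations import (
    ActivationSpec,
    ActivationState,
    elu_dx,
    leaky_relu_dx,
    mexican_hat,
    mexican_hat_dx,
    gaussian_basis,
    gaussian_basis_dx,
    prelu_da,
    relu_dx,
    srelu_dknots,
    srelu_dx,
)

__all__ = [
    "Layer",
    "InputCenter",
    "Conv2D",
    "Dense",
    "ActivationLayer",
    "AvgPool2D",
    "Upsample2D",
    "Flatten",
    "Softmax",
    "ModelGraph",
]


class Layer:
    """Base layer: forward caches what backward needs; params are numpy arrays."""

    kind = "layer"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def out_channels(self, in_channels: int) -> int:
        return in_channels

    def to_dict(self) -> dict:
        raise NotImplementedError


def _im2col(x, kh, kw, pad):
    """(N, C, H, W) -> (N, H, W, C*kh*kw) patches with zero 'same' padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, h, w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * kh * kw, h, w)


class Conv2D(Layer):
    """Same-padded stride-1 convolution, implemented by im2col."""

    kind = "conv"

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.weight = np.asarray(weight, dtype=np.float64)  # (F, C, kh, kw)
        self.bias = np.asarray(bias, dtype=np.float64)      # (F,)
        self._cache = None
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)

    @classmethod
    def init(cls, in_channels, out_channels, ksize, rng):
        fan_in = in_channels * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, ksize, ksize))
        return cls(w, np.zeros(out_channels))

    def forward(self, x, train=False):
        f, c, kh, kw = self.weight.shape
        pad = kh // 2
        cols = _im2col(x, kh, kw, pad)                        # (N, C*kh*kw, H, W)
        wmat = self.weight.reshape(f, -1)
        y = np.einsum("fk,nkhw->nfhw", wmat, cols) + self.bias[None, :, None, None]
        if train:
            self._cache = (x.shape, cols)
        return y

    def backward(self, grad):
        f, c, kh, kw = self.weight.shape
        pad = kh // 2
        x_shape, cols = self._cache
        self.d_weight = np.einsum("nfhw,nkhw->fk", grad, cols).reshape(self.weight.shape)
        self.d_bias = grad.sum(axis=(0, 2, 3))
        wmat = self.weight.reshape(f, -1)
        dcols = np.einsum("fk,nfhw->nkhw", wmat, grad)
        n, _, h, w = x_shape
        dcols = dcols.reshape(n, c, kh, kw, h, w)
        dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=grad.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dx[:, :, pad : pad + h, pad : pad + w]

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def grads(self):
        return {"weight": self.d_weight, "bias": self.d_bias}

    def out_channels(self, in_channels):
        return self.weight.shape[0]

    def to_dict(self):
        return {"kind": "conv", "weight": self.weight.tolist(), "bias": self.bias.tolist()}


class Dense(Layer):
    kind = "dense"

    def __init__(self, weight, bias):
        self.weight = np.asarray(weight, dtype=np.float64)  # (out, in)
        self.bias = np.asarray(bias, dtype=np.float64)
        self._x = None
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)

    @classmethod
    def init(cls, n_in, n_out, rng):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in))
        return cls(w, np.zeros(n_out))

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad):
        self.d_weight = grad.T @ self._x
        self.d_bias = grad.sum(axis=0)
        return grad @ self.weight

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def grads(self):
        return {"weight": self.d_weight, "bias": self.d_bias}

    def out_channels(self, in_channels):
        return self.weight.shape[0]

    def to_dict(self):
        return {"kind": "dense", "weight": self.weight.tolist(), "bias": self.bias.tolist()}


class ActivationLayer(Layer):
    """A replaceable activation slot: spec + learnable per-channel state.

    Parameters are per input channel for PReLU/APLU/MeLU/GaLU and per layer
    for SReLU's four knots.  ``backward`` accumulates gradients for the
    learnable fields by contracting the elementwise partials with the
    incoming gradient over batch and spatial axes.
    """

    kind = "activation"

    def __init__(self, spec: ActivationSpec, n_channels: int, rng=None,
                 state: Optional[ActivationState] = None):
        self.spec = spec
        self.n_channels = int(n_channels)
        self.state = state if state is not None else ActivationState.initial(
            spec, self.n_channels, rng)
        self._x = None
        self.d_state = {}

    def _bc(self, p, x, hinge=False):
        """Reshape (C,) or (C, n) parameter for broadcasting against x."""
        p = np.asarray(p, dtype=np.float64)
        if x.ndim == 4:
            if hinge:
                return p.reshape(self.n_channels, 1, 1, p.shape[-1])
            return p.reshape(self.n_channels, 1, 1)
        if x.ndim == 2:
            return p  # (N, C) dense features: (C,) / (C, n) broadcast as-is
        return p

    def forward(self, x, train=False):
        if train:
            self._x = x
        s, st = self.spec, self.state
        name = s.name
        if name == "ReLU":
            return np.maximum(x, 0.0)
        if name == "LeakyReLU":
            return np.where(x >= 0, x, s.leaky_a * x)
        if name == "ELU":
            return np.where(x >= 0, x, s.elu_a * np.expm1(np.minimum(x, 0.0)))
        if name == "PReLU":
            return np.where(x >= 0, x, self._bc(st.prelu_a, x) * x)
        if name == "SReLU":
            al, tl, ar, tr = st.srelu
            return np.where(x < tl, tl + al * (x - tl),
                            np.where(x > tr, tr + ar * (x - tr), x))
        if name == "APLU":
            a = self._bc(st.aplu_a, x, hinge=True)
            b = self._bc(st.aplu_b, x, hinge=True)
            xe = x[..., None]
            return np.maximum(x, 0.0) + np.sum(a * np.maximum(0.0, -xe + b), axis=-1)
        # basis families
        c = st.c
        if s.name in ("MeLU", "wMeLU"):
            basis = mexican_hat
        else:
            basis = gaussian_basis
        c0 = self._bc(c[:, 0], x)
        y = np.where(x >= 0, x, c0 * x)
        for j in range(1, s.k):
            cj = self._bc(c[:, j], x)
            y = y + cj * basis(x, s.alpha[j - 1], s.lam[j - 1], s.max_input)
        return y

    def _sum_axes(self, x):
        # contract everything except the channel axis
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def backward(self, grad):
        x = self._x
        s, st = self.spec, self.state
        name = s.name
        axes = self._sum_axes(x)
        self.d_state = {}
        if name == "ReLU":
            return grad * relu_dx(x)
        if name == "LeakyReLU":
            return grad * leaky_relu_dx(x, s.leaky_a)
        if name == "ELU":
            return grad * elu_dx(x, s.elu_a)
        if name == "PReLU":
            a = self._bc(st.prelu_a, x)
            self.d_state["prelu_a"] = np.sum(grad * prelu_da(x), axis=axes)
            return grad * np.where(x >= 0, 1.0, a)
        if name == "SReLU":
            dk = srelu_dknots(x, st.srelu)            # (4, *x)
            self.d_state["srelu"] = np.array([np.sum(grad * dk[i]) for i in range(4)])
            return grad * srelu_dx(x, st.srelu)
        if name == "APLU":
            a = self._bc(st.aplu_a, x, hinge=True)
            b = self._bc(st.aplu_b, x, hinge=True)
            xe = x[..., None]
            mask = xe < b
            ge = grad[..., None]
            self.d_state["aplu_a"] = np.sum(np.where(mask, ge * (-xe + b), 0.0),
                                            axis=axes).reshape(st.aplu_a.shape)
            self.d_state["aplu_b"] = np.sum(np.where(mask, ge * a, 0.0),
                                            axis=axes).reshape(st.aplu_b.shape)
            dx = np.where(x >= 0, 1.0, 0.0) + np.sum(np.where(mask, -a, 0.0), axis=-1)
            return grad * dx
        # basis families
        if s.name in ("MeLU", "wMeLU"):
            basis, basis_dx = mexican_hat, mexican_hat_dx
        else:
            basis, basis_dx = gaussian_basis, gaussian_basis_dx
        c = st.c
        c0 = self._bc(c[:, 0], x)
        dc = np.empty_like(c)
        dc[:, 0] = np.sum(grad * prelu_da(x), axis=axes)
        dx = np.where(x >= 0, 1.0, c0)
        for j in range(1, s.k):
            cj = self._bc(c[:, j], x)
            dc[:, j] = np.sum(grad * basis(x, s.alpha[j - 1], s.lam[j - 1], s.max_input),
                              axis=axes)
            dx = dx + cj * basis_dx(x, s.alpha[j - 1], s.lam[j - 1], s.max_input)
        self.d_state["c"] = dc
        return grad * dx

    def params(self):
        return dict(self.state.fields())

    def grads(self):
        return dict(self.d_state)

    def penalty(self):
        """L2 penalty contribution (APLU hinge slopes only)."""
        if self.spec.name == "APLU" and self.spec.l2_penalty > 0:
            return self.spec.l2_penalty * float(np.sum(self.state.aplu_a ** 2))
        return 0.0

    def penalty_grads(self):
        if self.spec.name == "APLU" and self.spec.l2_penalty > 0:
            return {"aplu_a": 2.0 * self.spec.l2_penalty * self.state.aplu_a}
        return {}

    def to_dict(self):
        d = {
            "kind": "activation",
            "spec": {
                "name": self.spec.name,
                "max_input": self.spec.max_input,
                "k": self.spec.k,
                "alpha": list(self.spec.alpha),
                "lam": list(self.spec.lam),
                "leaky_a": self.spec.leaky_a,
                "elu_a": self.spec.elu_a,
                "n_hinges": self.spec.n_hinges,
                "l2_penalty": self.spec.l2_penalty,
            },
            "n_channels": self.n_channels,
            "state": {k: v.tolist() for k, v in self.state.fields().items()},
        }
        return d


class InputCenter(Layer):
    """Fixed input shift (x - offset); centers [0, 1] images near zero.

    Not trainable; zero-centered inputs keep the early conv layers in the
    responsive region of the rectifier family and speed up from-scratch
    SGD markedly.
    """

    kind = "center"

    def __init__(self, offset: float = 0.5):
        self.offset = float(offset)

    def forward(self, x, train=False):
        return x - self.offset

    def backward(self, grad):
        return grad

    def to_dict(self):
        return {"kind": "center", "offset": self.offset}


class AvgPool2D(Layer):
    """2x2 average pooling with stride 2 (input H, W must be even)."""

    kind = "pool"

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if train:
            self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g

    def to_dict(self):
        return {"kind": "pool"}


class Upsample2D(Layer):
    """Nearest-neighbor 2x upsampling (decoder side of the segmenter)."""

    kind = "upsample"

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def to_dict(self):
        return {"kind": "upsample"}


class Flatten(Layer):
    kind = "flatten"

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def to_dict(self):
        return {"kind": "flatten"}


class Softmax(Layer):
    """Softmax over the class axis: axis 1 for both (N, K) and (N, K, H, W)."""

    kind = "softmax"

    def __init__(self):
        self._y = None

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=1, keepdims=True)
        if train:
            self._y = y
        return y

    def backward(self, grad):
        # full softmax Jacobian; training uses the fused CE shortcut instead
        y = self._y
        dot = np.sum(grad * y, axis=1, keepdims=True)
        return y * (grad - dot)

    def to_dict(self):
        return {"kind": "softmax"}


_LAYER_KINDS = {
    "pool": AvgPool2D,
    "upsample": Upsample2D,
    "flatten": Flatten,
    "softmax": Softmax,
}


class ModelGraph:
    """An ordered layer stack with enumerable activation slots."""

    def __init__(self, layers: Sequence[Layer], input_size):
        self.layers: List[Layer] = list(layers)
        self.input_size = tuple(input_size)  # (H, W, C)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=np.float64), train=False)

    def backward(self, grad: np.ndarray, upto: int = 0) -> np.ndarray:
        for layer in reversed(self.layers[upto:]):
            grad = layer.backward(grad)
        return grad

    def activation_slots(self) -> List[int]:
        return [i for i, l in enumerate(self.layers) if l.kind == "activation"]

    def slot_channels(self, slot: int) -> int:
        """Channel count feeding the activation at layer index ``slot``."""
        c = self.input_size[2]
        for layer in self.layers[:slot]:
            c = layer.out_channels(c)
        return c

    def weight_hash(self) -> str:
        """SHA-256 over all non-activation parameter blobs, in layer order."""
        h = hashlib.sha256()
        for layer in self.layers:
            if layer.kind == "activation":
                continue
            for name in sorted(layer.params()):
                arr = np.ascontiguousarray(layer.params()[name], dtype=np.float64)
                h.update(name.encode())
                h.update(arr.tobytes())
        return h.hexdigest()

    def copy(self) -> "ModelGraph":
        return ModelGraph.from_dict(self.to_dict())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "stochact-model-v1",
            "input_size": list(self.input_size),
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelGraph":
        if d.get("format") != "stochact-model-v1":
            raise ValueError("unrecognized model container format")
        layers = []
        for ld in d["layers"]:
            kind = ld["kind"]
            if kind == "conv":
                layers.append(Conv2D(np.array(ld["weight"]), np.array(ld["bias"])))
            elif kind == "dense":
                layers.append(Dense(np.array(ld["weight"]), np.array(ld["bias"])))
            elif kind == "activation":
                sd = dict(ld["spec"])
                sd["alpha"] = tuple(sd["alpha"])
                sd["lam"] = tuple(sd["lam"])
                spec = ActivationSpec(**sd)
                state = ActivationState(
                    **{k: np.array(v, dtype=np.float64) for k, v in ld["state"].items()}
                )
                layers.append(ActivationLayer(spec, ld["n_channels"], state=state))
            elif kind == "center":
                layers.append(InputCenter(ld["offset"]))
            elif kind in _LAYER_KINDS:
                layers.append(_LAYER_KINDS[kind]())
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
        return cls(layers, tuple(d["input_size"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ModelGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
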