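"""Minimal numpy neural-network backend.

A compact CPU backend providing exactly what the training schemes
need: convolution / dense / batch-norm / dropout layers with manual
backprop, an Adam optimizer with per-parameter-group learning rates,
and a multi-head block model whose ordered blocks can be frozen and
unfrozen by name and tapped by auxiliary branch heads.  Data layout is
NHWC.  It is deliberately small — tiny backbones on small synthetic
images — not a general-purpose framework.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .schedules import BackboneSpec

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "BatchNorm",
    "Dropout",
    "Sequential",
    "Block",
    "MultiHeadModel",
    "Adam",
    "softmax",
    "cross_entropy",
    "make_tiny_cnn",
]


class Param:
    """Trainable array with its gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: Optional[np.random.Generator] = None) -> None:
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (k * k * c_in))
        self.w = Param(rng.normal(0.0, scale, size=(k, k, c_in, c_out)), "conv_w")
        self.b = Param(np.zeros(c_out), "conv_b")
        self.k = k

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        pad = k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)), mode="constant")
        # (n, h, w, k, k, c)
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = cols.transpose(0, 1, 2, 4, 5, 3)
        self._cols = cols.reshape(n * h * w, k * k * c)
        self._xshape = x.shape
        out = self._cols @ self.w.value.reshape(k * k * c, -1) + self.b.value
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k = self.k
        pad = k // 2
        dflat = dout.reshape(n * h * w, -1)
        self.w.grad += (self._cols.T @ dflat).reshape(self.w.value.shape)
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.w.value.reshape(k * k * c, -1).T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad : pad + h, pad : pad + w, :]

    def params(self) -> List[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims assumed)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        d = self._mask * dout[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: Optional[np.random.Generator] = None) -> None:
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_in, d_out)), "dense_w")
        self.b = Param(np.zeros(d_out), "dense_b")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T

    def params(self) -> List[Param]:
        return [self.w, self.b]


class BatchNorm(Layer):
    """1-D batch normalisation with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(dim), "bn_gamma")
        self.beta = Param(np.zeros(dim), "bn_beta")
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        self.gamma.grad += (dout * self._xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        return (dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)) / self._std

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class Dropout(Layer):
    def __init__(self, p: float = 0.25, rng: Optional[np.random.Generator] = None) -> None:
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Block(Sequential):
    """Named backbone block group."""

    def __init__(self, name: str, layers: Sequence[Layer]) -> None:
        super().__init__(layers)
        self.name = name


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood; targets are integer class indices."""
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), targets] + eps).mean())


class MultiHeadModel:
    """Ordered backbone blocks with one or more classification heads.

    Heads attach either to the final block output (``tap=None``) or to
    an intermediate block's output (branch heads).  Blocks can be
    frozen by name: frozen blocks keep their parameters fixed and,
    when no trainable block precedes them, are skipped by backprop.
    """

    def __init__(
        self,
        blocks: Sequence[Block],
        heads: Mapping[str, Tuple[Optional[int], Sequential]],
        spec: BackboneSpec,
    ) -> None:
        self.blocks = list(blocks)
        self.heads = dict(heads)
        self.spec = spec
        self.trainable_blocks = {b.name for b in self.blocks}
        if [b.name for b in self.blocks] != list(spec.blocks):
            raise ValueError("block names must match the backbone spec order")

    def set_trainable(self, names: Sequence[str]) -> None:
        unknown = set(names) - {b.name for b in self.blocks}
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        self.trainable_blocks = set(names)

    def forward(self, x: np.ndarray, train: bool = False) -> Dict[str, np.ndarray]:
        taps: List[np.ndarray] = []
        for block in self.blocks:
            x = block.forward(x, train=train)
            taps.append(x)
        self._taps = taps
        out = {}
        for name, (tap, head) in self.heads.items():
            feat = taps[-1] if tap is None else taps[tap]
            out[name] = head.forward(feat, train=train)
        return out

    def backward(self, head_grads: Mapping[str, np.ndarray]) -> None:
        """Backprop per-head logit gradients through heads and blocks."""
        block_grads: List[Optional[np.ndarray]] = [None] * len(self.blocks)

        def add(idx: int, g: np.ndarray) -> None:
            block_grads[idx] = g if block_grads[idx] is None else block_grads[idx] + g

        for name, grad in head_grads.items():
            tap, head = self.heads[name]
            g = head.backward(grad)
            add(len(self.blocks) - 1 if tap is None else tap, g)

        # earliest block that still needs a parameter gradient
        trainable_idx = [i for i, b in enumerate(self.blocks) if b.name in self.trainable_blocks]
        stop = min(trainable_idx) if trainable_idx else len(self.blocks)
        carry: Optional[np.ndarray] = None
        for i in reversed(range(len(self.blocks))):
            g = block_grads[i]
            if carry is not None:
                g = carry if g is None else g + carry
            if g is None or i < stop:
                carry = None
                continue
            carry = self.blocks[i].backward(g)

    def zero_grad(self) -> None:
        for p in self.all_params():
            p.grad[...] = 0.0

    def all_params(self) -> List[Param]:
        params = [p for b in self.blocks for p in b.params()]
        for _, head in self.heads.values():
            params.extend(head.params())
        return params

    def param_groups(self, head_lr: float, body_lr: float) -> List[Tuple[List[Param], float]]:
        """(params, lr) groups: trainable blocks at body_lr, heads at head_lr."""
        groups = []
        body = [p for b in self.blocks if b.name in self.trainable_blocks for p in b.params()]
        if body:
            groups.append((body, body_lr))
        head_params = [p for _, head in self.heads.values() for p in head.params()]
        if head_params:
            groups.append((head_params, head_lr))
        return groups


class Adam:
    """Adam over (params, lr) groups."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: Dict[int, np.ndarray] = {}
        self._v: Dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, groups: Sequence[Tuple[Sequence[Param], float]]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for params, lr in groups:
            for p in params:
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p.value))
                v = self._v.setdefault(key, np.zeros_like(p.value))
                m[...] = b1 * m + (1 - b1) * p.grad
                v[...] = b2 * v + (1 - b2) * p.grad ** 2
                mhat = m / (1 - b1 ** self._t)
                vhat = v / (1 - b2 ** self._t)
                p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def make_dense_head(
    d_in: int,
    n_out: int,
    hidden: Sequence[int] = (),
    dropout: float = 0.0,
    batchnorm: bool = False,
    pool: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> Sequential:
    """Classifier head: optional GAP, then FC layers to ``n_out`` logits."""
    rng = rng or np.random.default_rng(0)
    layers: List[Layer] = [GlobalAvgPool()] if pool else []
    d = d_in
    for width in hidden:
        layers.append(Dense(d, width, rng=rng))
        if batchnorm:
            layers.append(BatchNorm(width))
        layers.append(ReLU())
        if dropout > 0:
            layers.append(Dropout(dropout, rng=rng))
        d = width
    layers.append(Dense(d, n_out, rng=rng))
    return Sequential(layers)


def make_tiny_cnn(
    n_classes: int = 13,
    channels: Sequence[int] = (8, 16, 32),
    image_channels: int = 3,
    seed: int = 0,
    head_hidden: Sequence[int] = (),
    extra_heads: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> Tuple[MultiHeadModel, BackboneSpec]:
    """Tiny convolutional backbone for desk-scale experiments.

    One block per entry of ``channels`` (conv + ReLU + 2x2 pool), a
    global-average-pooled dense head named ``"dx"``, and optional extra
    heads given as ``name -> (tap_block_index, n_categories)``.
    """
    rng = np.random.default_rng(seed)
    blocks: List[Block] = []
    c_prev = image_channels
    for i, c in enumerate(channels):
        blocks.append(Block(f"block{i + 1}", [Conv2d(c_prev, c, rng=rng), ReLU(), MaxPool2()]))
        c_prev = c
    insertion = {name: tap for name, (tap, _) in (extra_heads or {}).items()}
    spec = BackboneSpec(
        blocks=tuple(b.name for b in blocks), feature_dim=channels[-1], insertion_points=insertion
    )
    heads: Dict[str, Tuple[Optional[int], Sequential]] = {
        "dx": (None, make_dense_head(channels[-1], n_classes, hidden=head_hidden, rng=rng))
    }
    for name, (tap, n_cat) in (extra_heads or {}).items():
        heads[name] = (tap, make_dense_head(channels[tap], n_cat, hidden=(16,), rng=rng))
    return MultiHeadModel(blocks, heads, spec), spec
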