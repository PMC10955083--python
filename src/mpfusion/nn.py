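"""Minimal differentiable neural-network toolkit on top of autograd/numpy.

All tensors are NHWC: ``[batch, height, width, channels]``.  Layers follow a
functional convention — ``layer.init(rng)`` returns a (possibly nested)
parameter container of plain numpy arrays, and ``layer(params, x)`` is a pure
function of both, so :func:`autograd.grad` can differentiate a loss with
respect to the parameter tree.

Convolutions are implemented as patch extraction (im2col) followed by a
tensor contraction, which keeps both the forward and the autograd-generated
backward pass inside BLAS.  Batch normalisation always uses the statistics of
the current batch; there is no running-average state, so every forward pass
is a pure function (see docs/methods.md for the trade-off).
"""

from __future__ import annotations

import autograd.numpy as np
import numpy as onp

__all__ = [
    "conv2d", "depthwise_conv2d", "max_pool", "avg_pool", "global_avg_pool",
    "dense", "relu", "sigmoid", "softmax", "log_softmax", "batch_norm",
    "Layer", "Conv2D", "DepthwiseConv2D", "Dense", "BatchNorm", "ReLU",
    "MaxPool", "AvgPool", "GlobalAvgPool", "Sequential", "Identity",
    "tree_map", "tree_map2", "tree_leaves", "count_params", "l1_penalty",
    "sgd_step", "cross_entropy",
]


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _same_pad(n, k, s):
    """Total padding along one axis for 'same' output size ceil(n/s)."""
    out = -(-n // s)
    return max((out - 1) * s + k - n, 0)


def _patches(x, kh, kw, sh, sw, padding):
    """Extract sliding windows -> [B, OH, OW, kh, kw, C]."""
    B, H, W, C = x.shape
    if padding == "same":
        ph, pw = _same_pad(H, kh, sh), _same_pad(W, kw, sw)
        # autograd's pad vjp requires the mode argument to be explicit
        x = np.pad(x, ((0, 0), (ph // 2, ph - ph // 2),
                       (pw // 2, pw - pw // 2), (0, 0)), "constant")
        H, W = H + ph, W + pw
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    oh = (H - kh) // sh + 1
    ow = (W - kw) // sw + 1
    i = (onp.arange(oh) * sh)[:, None, None, None] + onp.arange(kh)[None, None, :, None]
    j = (onp.arange(ow) * sw)[None, :, None, None] + onp.arange(kw)[None, None, None, :]
    i = onp.broadcast_to(i, (oh, ow, kh, kw))
    j = onp.broadcast_to(j, (oh, ow, kh, kw))
    return x[:, i, j, :]


def conv2d(x, w, b=None, stride=1, padding="same"):
    """2-D convolution (cross-correlation). w: [kh, kw, Cin, Cout]."""
    kh, kw, cin, cout = w.shape
    sh, sw = _pair(stride)
    if kh == 1 and kw == 1 and sh == 1 and sw == 1:
        y = np.tensordot(x, w[0, 0], (3, 0))
    else:
        p = _patches(x, kh, kw, sh, sw, padding)
        y = np.tensordot(p, w, ((3, 4, 5), (0, 1, 2)))
    if b is not None:
        y = y + b
    return y


def depthwise_conv2d(x, w, b=None, stride=1, padding="same"):
    """Per-channel convolution. w: [kh, kw, C]."""
    kh, kw, c = w.shape
    sh, sw = _pair(stride)
    p = _patches(x, kh, kw, sh, sw, padding)            # [B,OH,OW,kh,kw,C]
    y = np.sum(p * w[None, None, None], axis=(3, 4))
    if b is not None:
        y = y + b
    return y


def max_pool(x, size=2, stride=None, padding="valid"):
    k = _pair(size)
    s = _pair(stride) if stride is not None else k
    p = _patches(x, k[0], k[1], s[0], s[1], padding)
    return np.max(p, axis=(3, 4))


def avg_pool(x, size=2, stride=None, padding="valid"):
    k = _pair(size)
    s = _pair(stride) if stride is not None else k
    p = _patches(x, k[0], k[1], s[0], s[1], padding)
    return np.mean(p, axis=(3, 4))


def global_avg_pool(x, keepdims=False):
    return np.mean(x, axis=(1, 2), keepdims=keepdims)


def dense(x, w, b=None):
    y = np.dot(x, w)
    return y + b if b is not None else y


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def softmax(x, axis=-1):
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    z = x - np.max(x, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def batch_norm(x, gamma, beta, eps=1e-5):
    axes = tuple(range(x.ndim - 1))
    mu = np.mean(x, axis=axes, keepdims=True)
    var = np.mean((x - mu) ** 2, axis=axes, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def cross_entropy(logits, y):
    """Mean negative log-likelihood of integer labels y under the logits."""
    lp = log_softmax(logits, axis=-1)
    return -np.mean(lp[np.arange(logits.shape[0]), y])


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class: ``init(rng) -> params``; ``layer(params, x) -> y``."""

    def init(self, rng):
        return {}

    def apply(self, params, x):
        raise NotImplementedError

    def __call__(self, params, x):
        return self.apply(params, x)


class Conv2D(Layer):
    def __init__(self, cin, cout, kernel=3, stride=1, padding="same",
                 use_bias=True):
        self.cin, self.cout = cin, cout
        self.kh, self.kw = _pair(kernel)
        self.stride, self.padding, self.use_bias = stride, padding, use_bias

    def init(self, rng):
        fan_in = self.kh * self.kw * self.cin
        w = rng.normal(0.0, onp.sqrt(2.0 / fan_in),
                       (self.kh, self.kw, self.cin, self.cout))
        p = {"w": w}
        if self.use_bias:
            p["b"] = onp.zeros(self.cout)
        return p

    def apply(self, params, x):
        return conv2d(x, params["w"], params.get("b"),
                      self.stride, self.padding)


class DepthwiseConv2D(Layer):
    def __init__(self, channels, kernel=3, stride=1, padding="same",
                 use_bias=True):
        self.channels = channels
        self.kh, self.kw = _pair(kernel)
        self.stride, self.padding, self.use_bias = stride, padding, use_bias

    def init(self, rng):
        fan_in = self.kh * self.kw
        p = {"w": rng.normal(0.0, onp.sqrt(2.0 / fan_in),
                             (self.kh, self.kw, self.channels))}
        if self.use_bias:
            p["b"] = onp.zeros(self.channels)
        return p

    def apply(self, params, x):
        return depthwise_conv2d(x, params["w"], params.get("b"),
                                self.stride, self.padding)


class Dense(Layer):
    def __init__(self, nin, nout, use_bias=True):
        self.nin, self.nout, self.use_bias = nin, nout, use_bias

    def init(self, rng):
        bound = onp.sqrt(6.0 / (self.nin + self.nout))
        p = {"w": rng.uniform(-bound, bound, (self.nin, self.nout))}
        if self.use_bias:
            p["b"] = onp.zeros(self.nout)
        return p

    def apply(self, params, x):
        return dense(x, params["w"], params.get("b"))


class BatchNorm(Layer):
    def __init__(self, channels, eps=1e-5):
        self.channels, self.eps = channels, eps

    def init(self, rng):
        return {"gamma": onp.ones(self.channels),
                "beta": onp.zeros(self.channels)}

    def apply(self, params, x):
        return batch_norm(x, params["gamma"], params["beta"], self.eps)


class ReLU(Layer):
    def apply(self, params, x):
        return relu(x)


class MaxPool(Layer):
    def __init__(self, size=2, stride=None, padding="valid"):
        self.size, self.stride, self.padding = size, stride, padding

    def apply(self, params, x):
        return max_pool(x, self.size, self.stride, self.padding)


class AvgPool(Layer):
    def __init__(self, size=2, stride=None, padding="valid"):
        self.size, self.stride, self.padding = size, stride, padding

    def apply(self, params, x):
        return avg_pool(x, self.size, self.stride, self.padding)


class GlobalAvgPool(Layer):
    """Spatial mean; with keepdims the output is [B, 1, 1, C]."""

    def __init__(self, keepdims=True):
        self.keepdims = keepdims

    def apply(self, params, x):
        return global_avg_pool(x, keepdims=self.keepdims)


class Identity(Layer):
    def apply(self, params, x):
        return x


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def init(self, rng):
        return [layer.init(rng) for layer in self.layers]

    def apply(self, params, x):
        for layer, p in zip(self.layers, params):
            x = layer(p, x)
        return x


# ---------------------------------------------------------------------------
# parameter-tree utilities
# ---------------------------------------------------------------------------

def tree_map(f, tree):
    if isinstance(tree, dict):
        return {k: tree_map(f, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return [tree_map(f, v) for v in tree]
    return f(tree)


def tree_map2(f, a, b):
    if isinstance(a, dict):
        return {k: tree_map2(f, a[k], b[k]) for k in a}
    if isinstance(a, (list, tuple)):
        return [tree_map2(f, x, y) for x, y in zip(a, b)]
    return f(a, b)


def tree_leaves(tree, key=None):
    """Yield (leaf_name, array) pairs for every array in the tree."""
    if isinstance(tree, dict):
        for k, v in tree.items():
            yield from tree_leaves(v, k)
    elif isinstance(tree, (list, tuple)):
        for v in tree:
            yield from tree_leaves(v, key)
    else:
        yield key, tree


def count_params(tree):
    return int(sum(onp.asarray(v).size for _, v in tree_leaves(tree)))


def l1_penalty(tree):
    """Sum of |w| over weight kernels only (biases and norm params excluded)."""
    total = 0.0
    for name, leaf in tree_leaves(tree):
        if name == "w":
            total = total + np.sum(np.abs(leaf))
    return total


def sgd_step(params, grads, lr):
    return tree_map2(lambda p, g: p - lr * g, params, grads)
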