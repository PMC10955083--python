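"""Per-modality convolutional feature extractors.

Two independent branches (one per MRI sequence) each turn a
``[B, 224, 224, 3]`` batch into a ``[B, 7, 7, C]`` feature map; the default
dense-connectivity backbone (DenseNet121 topology) yields ``C = 1024``.  A
``compact-test`` backbone with three conv/pool stages and 64 output channels
is provided so the full fusion graph trains in seconds on a CPU.

Extractors are truncated before any classification head.  Weights are
randomly initialised from a stated seed; ``pretrained=True`` asks for
externally supplied weights (via ``weights_file``) and never triggers a
download.
"""

from __future__ import annotations

import pickle

import autograd.numpy as np
import numpy as onp

from . import nn

__all__ = ["build_extractor", "extract_pair", "Extractor", "ARCH_REGISTRY"]


# ---------------------------------------------------------------------------
# dense-connectivity backbone (DenseNet121 topology)
# ---------------------------------------------------------------------------

class _DenseLayer(nn.Layer):
    """BN-ReLU-1x1(4g) -> BN-ReLU-3x3(g), input concatenated with output."""

    def __init__(self, cin, growth):
        self.inner = nn.Sequential(
            nn.BatchNorm(cin), nn.ReLU(),
            nn.Conv2D(cin, 4 * growth, 1, use_bias=False),
            nn.BatchNorm(4 * growth), nn.ReLU(),
            nn.Conv2D(4 * growth, growth, 3, use_bias=False),
        )

    def init(self, rng):
        return self.inner.init(rng)

    def apply(self, params, x):
        return np.concatenate([x, self.inner(params, x)], axis=3)


class _DenseBlock(nn.Layer):
    def __init__(self, cin, n_layers, growth=32):
        self.layers = [_DenseLayer(cin + i * growth, growth)
                       for i in range(n_layers)]
        self.cout = cin + n_layers * growth

    def init(self, rng):
        return [layer.init(rng) for layer in self.layers]

    def apply(self, params, x):
        for layer, p in zip(self.layers, params):
            x = layer(p, x)
        return x


def _transition(cin):
    return nn.Sequential(nn.BatchNorm(cin), nn.ReLU(),
                         nn.Conv2D(cin, cin // 2, 1, use_bias=False),
                         nn.AvgPool(2))


def _densenet121():
    layers = [nn.Conv2D(3, 64, 7, stride=2, use_bias=False),
              nn.BatchNorm(64), nn.ReLU(),
              nn.MaxPool(3, 2, padding="same")]
    c = 64
    for i, n in enumerate([6, 12, 24, 16]):
        block = _DenseBlock(c, n)
        layers.append(block)
        c = block.cout
        if i < 3:
            layers.append(_transition(c))
            c //= 2
    layers += [nn.BatchNorm(c), nn.ReLU()]
    return nn.Sequential(*layers), c          # c = 1024


# ---------------------------------------------------------------------------
# residual backbone (ResNet50 topology)
# ---------------------------------------------------------------------------

class _Bottleneck(nn.Layer):
    def __init__(self, cin, cmid, cout, stride=1):
        self.main = nn.Sequential(
            nn.Conv2D(cin, cmid, 1, use_bias=False), nn.BatchNorm(cmid), nn.ReLU(),
            nn.Conv2D(cmid, cmid, 3, stride=stride, use_bias=False),
            nn.BatchNorm(cmid), nn.ReLU(),
            nn.Conv2D(cmid, cout, 1, use_bias=False), nn.BatchNorm(cout),
        )
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = nn.Sequential(
                nn.Conv2D(cin, cout, 1, stride=stride, use_bias=False),
                nn.BatchNorm(cout))

    def init(self, rng):
        p = {"main": self.main.init(rng)}
        if self.proj is not None:
            p["proj"] = self.proj.init(rng)
        return p

    def apply(self, params, x):
        y = self.main(params["main"], x)
        sc = x if self.proj is None else self.proj(params["proj"], x)
        return nn.relu(y + sc)


def _resnet50():
    layers = [nn.Conv2D(3, 64, 7, stride=2, use_bias=False),
              nn.BatchNorm(64), nn.ReLU(),
              nn.MaxPool(3, 2, padding="same")]
    c = 64
    for stage, (n, cmid) in enumerate([(3, 64), (4, 128), (6, 256), (3, 512)]):
        cout = cmid * 4
        for i in range(n):
            stride = 2 if (i == 0 and stage > 0) else 1
            layers.append(_Bottleneck(c, cmid, cout, stride))
            c = cout
    return nn.Sequential(*layers), c          # c = 2048


# ---------------------------------------------------------------------------
# depthwise-separable backbone ("xception-like", simplified)
# ---------------------------------------------------------------------------

def _sep_conv(cin, cout):
    return nn.Sequential(nn.DepthwiseConv2D(cin, 3, use_bias=False),
                         nn.Conv2D(cin, cout, 1, use_bias=False),
                         nn.BatchNorm(cout), nn.ReLU())


def _xception_like():
    layers = [nn.Conv2D(3, 32, 3, stride=2, use_bias=False),
              nn.BatchNorm(32), nn.ReLU(),
              nn.Conv2D(32, 64, 3, use_bias=False),
              nn.BatchNorm(64), nn.ReLU()]
    c = 64
    for cout in [128, 256, 512, 1024]:
        layers += [_sep_conv(c, cout), _sep_conv(cout, cout), nn.MaxPool(2)]
        c = cout
    return nn.Sequential(*layers), c          # c = 1024


def _compact_test():
    layers = []
    c = 3
    for cout in [16, 32, 64]:
        layers += [nn.Conv2D(c, cout, 3), nn.BatchNorm(cout), nn.ReLU(),
                   nn.MaxPool(2)]
        c = cout
    layers.append(nn.GlobalAvgPool(keepdims=True))   # -> [B,1,1,64]
    return nn.Sequential(*layers), 64


ARCH_REGISTRY = {
    "densenet121": _densenet121,
    "resnet50": _resnet50,
    "xception-like": _xception_like,
    "compact-test": _compact_test,
}


class Extractor:
    """A truncated feature extractor with its own parameter set.

    Callable as ``extractor(x)`` with the stored parameters or
    ``extractor(x, params)`` with an explicit (e.g. in-training) tree.
    Input and output are NHWC.
    """

    def __init__(self, name, net, out_channels, params):
        self.name = name
        self.net = net
        self.out_channels = out_channels
        self.params = params

    def init(self, seed):
        self.params = self.net.init(onp.random.default_rng(seed))
        return self.params

    def __call__(self, x, params=None):
        x = np.asarray(x)
        if x.ndim != 4:
            raise ValueError(f"expected NHWC batch, got shape {x.shape}")
        return self.net(self.params if params is None else params, x)


def build_extractor(arch_name, pretrained=False, seed=0, weights_file=None):
    """Build a per-modality feature extractor from the architecture registry.

    Parameters
    ----------
    arch_name : one of ``densenet121`` (default backbone), ``resnet50``,
        ``xception-like``, ``compact-test``.
    pretrained : request externally supplied weights.  ``weights_file`` must
        then point to a pickled parameter tree from a previous session;
        nothing is ever downloaded.
    seed : RNG seed for random initialisation when not pretrained.
    """
    if arch_name not in ARCH_REGISTRY:
        raise ValueError(f"unknown architecture {arch_name!r}; "
                         f"choose from {sorted(ARCH_REGISTRY)}")
    if pretrained and arch_name == "compact-test":
        raise ValueError("compact-test has no pretrained weights")
    net, cout = ARCH_REGISTRY[arch_name]()
    if pretrained:
        if weights_file is None:
            raise ValueError("pretrained=True requires weights_file; "
                             "weights are never downloaded")
        with open(weights_file, "rb") as fh:
            params = pickle.load(fh)
    else:
        params = net.init(onp.random.default_rng(seed))
    return Extractor(arch_name, net, cout, params)


def extract_pair(batch, extractor_a, extractor_b,
                 params_a=None, params_b=None):
    """Run the two modality branches of a paired batch independently.

    ``batch`` is a pair ``(X1, X2)`` of NHWC arrays (modality A = T2WI-like,
    modality B = DCE-like).  The branches must not share parameters.
    """
    x1, x2 = batch
    x1, x2 = np.asarray(x1), np.asarray(x2)
    if x1.shape != x2.shape:
        raise ValueError(f"modality shape mismatch: {x1.shape} vs {x2.shape}")
    if extractor_a.params is extractor_b.params:
        raise ValueError("branches must have independent parameters")
    return (extractor_a(x1, params_a), extractor_b(x2, params_b))
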