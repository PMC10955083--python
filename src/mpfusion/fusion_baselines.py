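"""Fusion strategies: the SAFF network and the three comparison baselines.

All four strategies share the same backbones, optional MA blocks and
training loop, so a strategy comparison is one configuration switch:

* ``input_level`` — both modality images are pooled into one single-modality
  dataset (sample pooling doubles the sample count) and a single shared
  network is trained on the pool;
* ``feature_level`` — per-branch pooled feature vectors are combined by
  channel concatenation or elementwise addition before the classifier;
* ``decision_level`` — two independently trained single-modality networks
  vote with (by default validation-accuracy-proportional) soft weights;
* ``saff`` — the self-attention token-fusion head of :mod:`mpfusion.saff`.
"""

from __future__ import annotations

import autograd.numpy as np
import numpy as onp

from . import nn
from .backbone import ARCH_REGISTRY
from .ma_block import MABlock, MAConfig
from .saff import SAFFHead

__all__ = [
    "input_level_dataset", "feature_level_fuse", "decision_level_fuse",
    "Branch", "SingleModalityNet", "FeatureLevelNet", "SMMFNet",
    "build_model",
]


# ---------------------------------------------------------------------------
# strategy primitives
# ---------------------------------------------------------------------------

def input_level_dataset(x1, x2, y, patient_ids=None):
    """Pool paired modalities into a single-modality dataset.

    Every modality image becomes an independent sample carrying its slice's
    label; patient ids are carried along so downstream splits stay
    leakage-free.  N pairs in -> 2N samples out.
    """
    x = np.concatenate([x1, x2], axis=0)
    yy = np.concatenate([y, y], axis=0)
    if patient_ids is None:
        return x, yy
    pids = onp.concatenate([patient_ids, patient_ids], axis=0)
    return x, yy, pids


def feature_level_fuse(feat_a, feat_b, mode="concat"):
    """Combine two branch features: 'concat' doubles the channel axis,
    'add' sums elementwise."""
    if mode == "concat":
        return np.concatenate([feat_a, feat_b], axis=-1)
    if mode == "add":
        if feat_a.shape != feat_b.shape:
            raise ValueError("'add' requires identical shapes")
        return feat_a + feat_b
    raise ValueError(f"unknown feature fusion mode {mode!r}")


def decision_level_fuse(probs_a, probs_b, weights=None, mode="soft"):
    """Fuse two per-branch class-probability arrays.

    ``soft`` (default): renormalised weighted average of the probability
    vectors.  ``vote``: hard majority over an arbitrary list of classifier
    outputs (pass a list/tuple as ``probs_a`` and None for ``probs_b``),
    ties broken by the mean probability.
    """
    if mode == "vote":
        members = list(probs_a) if probs_b is None else [probs_a, probs_b]
        votes = onp.stack([onp.argmax(onp.asarray(p), axis=1)
                           for p in members])
        mean_p = onp.mean([onp.asarray(p) for p in members], axis=0)
        n = votes.shape[0]
        frac1 = votes.sum(axis=0) / n
        out = onp.where(frac1 > 0.5, 1, onp.where(frac1 < 0.5, 0,
                        onp.argmax(mean_p, axis=1)))
        probs = onp.zeros_like(mean_p)
        probs[onp.arange(len(out)), out] = 1.0
        return probs
    if weights is None:
        weights = (0.5, 0.5)
    w = onp.asarray(weights, dtype=float)
    if onp.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("weights sum to zero")
    w = w / w.sum()
    return w[0] * probs_a + w[1] * probs_b


# ---------------------------------------------------------------------------
# trainable networks (shared Branch + strategy heads)
# ---------------------------------------------------------------------------

class Branch:
    """One modality branch: backbone (from the architecture registry) plus
    an optional MA block."""

    def __init__(self, arch="compact-test", use_ma=False, ma_cfg=None):
        self.net, self.cout = ARCH_REGISTRY[arch]()
        self.ma = None
        if use_ma:
            cfg = ma_cfg or MAConfig(in_channels=self.cout,
                                     cbam_reduction=min(16, self.cout // 4))
            self.ma = MABlock(cfg)
        self.out_dim = self.ma.out_channels if self.ma else self.cout

    def init(self, rng):
        p = {"ext": self.net.init(rng)}
        if self.ma:
            p["ma"] = self.ma.init(rng)
        return p

    def fmap(self, params, x):
        y = self.net(params["ext"], x)
        if self.ma:
            y = self.ma(params["ma"], y)
        return y

    def vec(self, params, x):
        return np.mean(self.fmap(params, x), axis=(1, 2))


class _TwoFC(nn.Layer):
    def __init__(self, nin, hidden, n_classes=2):
        self.fc1 = nn.Dense(nin, hidden)
        self.fc2 = nn.Dense(hidden, n_classes)

    def init(self, rng):
        return {"fc1": self.fc1.init(rng), "fc2": self.fc2.init(rng)}

    def apply(self, params, x):
        return self.fc2(params["fc2"], nn.relu(self.fc1(params["fc1"], x)))


class _Model:
    """Common interface: init(seed) -> params; logits(params, x1, x2)."""

    def init(self, seed):
        raise NotImplementedError

    def logits(self, params, x1, x2):
        raise NotImplementedError

    def predict_proba(self, params, x1, x2):
        return onp.asarray(nn.softmax(self.logits(params, x1, x2), axis=-1))


class SingleModalityNet(_Model):
    """One branch + two-FC classifier; ``modality`` picks the input slot
    ('a', 'b', or 'pooled' for input-level fusion where x1 carries the
    pooled samples)."""

    def __init__(self, arch="compact-test", modality="a", use_ma=False,
                 ma_cfg=None, hidden=64):
        self.modality = modality
        self.branch = Branch(arch, use_ma, ma_cfg)
        self.head = _TwoFC(self.branch.out_dim, hidden)

    def init(self, seed):
        rng = onp.random.default_rng(seed)
        return {"branch": self.branch.init(rng), "head": self.head.init(rng)}

    def logits(self, params, x1, x2):
        x = x2 if self.modality == "b" else x1
        return self.head(params["head"], self.branch.vec(params["branch"], x))


class FeatureLevelNet(_Model):
    def __init__(self, arch="compact-test", mode="concat", use_ma=False,
                 ma_cfg=None, hidden=64):
        self.mode = mode
        self.branch_a = Branch(arch, use_ma, ma_cfg)
        self.branch_b = Branch(arch, use_ma, ma_cfg)
        nin = (self.branch_a.out_dim * 2 if mode == "concat"
               else self.branch_a.out_dim)
        self.head = _TwoFC(nin, hidden)

    def init(self, seed):
        rng = onp.random.default_rng(seed)
        return {"a": self.branch_a.init(rng), "b": self.branch_b.init(rng),
                "head": self.head.init(rng)}

    def logits(self, params, x1, x2):
        va = self.branch_a.vec(params["a"], x1)
        vb = self.branch_b.vec(params["b"], x2)
        return self.head(params["head"],
                         feature_level_fuse(va, vb, self.mode))


class SMMFNet(_Model):
    """The full fusion network: two independent branches (backbone + MA)
    and the SAFF token-fusion head."""

    def __init__(self, arch="compact-test", use_ma=True, ma_cfg=None,
                 theta=1.0, theta_learnable=False, readout="full",
                 hidden=64):
        self.branch_a = Branch(arch, use_ma, ma_cfg)
        self.branch_b = Branch(arch, use_ma, ma_cfg)
        self.head = SAFFHead(d=self.branch_a.out_dim, theta=theta,
                             theta_learnable=theta_learnable,
                             readout=readout, hidden=hidden)

    def init(self, seed):
        rng = onp.random.default_rng(seed)
        return {"a": self.branch_a.init(rng), "b": self.branch_b.init(rng),
                "head": self.head.init(rng)}

    def logits(self, params, x1, x2):
        fa = self.branch_a.fmap(params["a"], x1)
        fb = self.branch_b.fmap(params["b"], x2)
        return self.head.apply(params["head"], (fa, fb))


def build_model(strategy, **kwargs):
    """Model factory keyed by fusion strategy name."""
    if strategy in ("single_a", "single_b"):
        return SingleModalityNet(modality=strategy[-1], **kwargs)
    if strategy == "input_level":
        return SingleModalityNet(modality="pooled", **kwargs)
    if strategy == "feature_level":
        return FeatureLevelNet(**kwargs)
    if strategy == "saff":
        return SMMFNet(**kwargs)
    raise ValueError(f"unknown strategy {strategy!r}")
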