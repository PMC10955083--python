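"""Self-Attention Feature Fusion (SAFF) head and two-FC classifier.

Each modality branch is globally average-pooled to a single d-dimensional
token; the two modality tokens and a learnable class token are stacked into
a ``[B, 3, d]`` bundle (row order: modality A, modality B, cls).  Single-head
scaled dot-product attention then produces

    g = softmax(Q K^T / sqrt(d))      modality-specificity matrix, [B, 3, 3]
    f = g V                           attended (common) features,  [B, 3, d]
    h = theta * V + f                 residual-enriched features,  [B, 3, d]

with Q = T Wq, K = T Wk, V = T Wv and a nonnegative residual coefficient
theta.  The specific (g) and common (h) features are then spliced into one
fused vector p — either the full flattened pair (``readout='full'``,
length 3d+9) or the class-token rows only (``readout='cls'``, length d+3) —
and classified by two fully connected layers with softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as np
import numpy as onp

from . import nn

__all__ = [
    "pool_and_tokenize", "assemble_tokens", "attention_matrix",
    "common_features", "fuse", "FusionOutput", "SAFFHead",
]


@dataclass
class FusionOutput:
    """Intermediate fusion quantities: attention matrix ``g`` [B,3,3],
    attended features ``f`` [B,3,d], residual-enriched ``h`` [B,3,d] and the
    fused vector ``p``."""

    g: object
    f: object
    h: object
    p: object


def pool_and_tokenize(fmap):
    """[B, H, W, C] feature map -> [B, 1, C] token by spatial mean."""
    if fmap.shape[1] == 0 or fmap.shape[2] == 0:
        raise ValueError("feature map has zero spatial extent")
    return np.mean(fmap, axis=(1, 2))[:, None, :]


def assemble_tokens(token_a, token_b, cls_token):
    """Stack (token_A, token_B, cls) into a [B, 3, d] bundle.

    ``cls_token`` is a length-d vector broadcast across the batch."""
    if token_a.shape[2] != token_b.shape[2] or token_a.shape[2] != cls_token.shape[-1]:
        raise ValueError("token dimension mismatch")
    b = token_a.shape[0]
    cls = np.reshape(cls_token, (1, 1, -1)) * np.ones((b, 1, 1))
    return np.concatenate([token_a, token_b, cls], axis=1)


def attention_matrix(q, k, d=None):
    """Row-softmax of Q K^T / sqrt(d) over the key axis -> [B, 3, 3]."""
    if d is None:
        d = q.shape[-1]
    logits = np.einsum("bid,bjd->bij", q, k) / np.sqrt(float(d))
    return nn.softmax(logits, axis=-1)


def common_features(g, v, theta):
    """f = g V (attended common features); h = theta * V + f."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    f = np.einsum("bij,bjd->bid", g, v)
    return f, theta * v + f


def fuse(g, h, readout="full"):
    """Splice specificity (g) and commonality (h) into the fused vector p.

    ``full``: flatten both and concatenate -> length 3d + 9.
    ``cls``: the class-token rows only, h-row then g-row -> length d + 3.
    """
    b = g.shape[0]
    if readout == "full":
        return np.concatenate([np.reshape(g, (b, -1)),
                               np.reshape(h, (b, -1))], axis=1)
    if readout == "cls":
        return np.concatenate([h[:, 2, :], g[:, 2, :]], axis=1)
    raise ValueError(f"unknown readout {readout!r}")


class SAFFHead(nn.Layer):
    """Learnable SAFF fusion head: Wq/Wk/Wv projections, a class token, the
    residual coefficient theta, and the two-FC classifier.

    Parameters
    ----------
    d : token dimension (must equal the MA output channel count).
    theta : residual coefficient for the original value features (>= 0).
    theta_learnable : update theta by gradient descent.
    readout : ``full`` (default) or ``cls``.
    hidden : width of the first fully connected layer.
    n_classes : output classes (2: low-grade vs high-grade).
    """

    def __init__(self, d, theta=1.0, theta_learnable=False, readout="full",
                 hidden=256, n_classes=2, dropout=0.0):
        if theta < 0:
            raise ValueError("theta must be nonnegative")
        if readout not in ("full", "cls"):
            raise ValueError(f"unknown readout {readout!r}")
        self.d = d
        self.theta = theta
        self.theta_learnable = theta_learnable
        self.readout = readout
        self.dropout = dropout
        p_len = 3 * d + 9 if readout == "full" else d + 3
        self.fc1 = nn.Dense(p_len, hidden)
        self.fc2 = nn.Dense(hidden, n_classes)

    def init(self, rng):
        d = self.d
        bound = onp.sqrt(6.0 / (2 * d))
        p = {"wq": rng.uniform(-bound, bound, (d, d)),
             "wk": rng.uniform(-bound, bound, (d, d)),
             "wv": rng.uniform(-bound, bound, (d, d)),
             "cls": rng.normal(0.0, 0.02, d),
             "fc1": self.fc1.init(rng), "fc2": self.fc2.init(rng)}
        if self.theta_learnable:
            p["theta"] = onp.asarray(float(self.theta))
        return p

    def _theta(self, params):
        return params["theta"] if self.theta_learnable else self.theta

    def fusion(self, params, token_a, token_b):
        """Full Eq-chain on a token pair -> :class:`FusionOutput`."""
        t = assemble_tokens(token_a, token_b, params["cls"])
        q = np.einsum("bnd,de->bne", t, params["wq"])
        k = np.einsum("bnd,de->bne", t, params["wk"])
        v = np.einsum("bnd,de->bne", t, params["wv"])
        g = attention_matrix(q, k, self.d)
        f, h = common_features(g, v, self._theta(params))
        p = fuse(g, h, self.readout)
        return FusionOutput(g=g, f=f, h=h, p=p)

    def classify(self, params, p, rng=None):
        """Two-FC classifier -> logits [B, n_classes]."""
        z = nn.relu(self.fc1(params["fc1"], p))
        if self.dropout > 0 and rng is not None:
            mask = rng.random(z.shape) >= self.dropout
            z = z * mask / (1.0 - self.dropout)
        return self.fc2(params["fc2"], z)

    def apply(self, params, fmaps, rng=None):
        """(fmap_a, fmap_b) -> logits; pools, fuses and classifies."""
        fa, fb = fmaps
        out = self.fusion(params, pool_and_tokenize(fa), pool_and_tokenize(fb))
        return self.classify(params, out.p, rng)

    def predict_proba(self, params, fmaps):
        return nn.softmax(self.apply(params, fmaps), axis=-1)
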