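"""SAFF head: pooling, token assembly, attention equations and classifier,
checked against naive-loop oracles and finite differences."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad
from hypothesis import given, settings, strategies as st

from mpfusion import nn, saff
from mpfusion.saff import (SAFFHead, assemble_tokens, attention_matrix,
                           common_features, fuse, pool_and_tokenize)


# ---------------------------------------------------------------------------
# naive-loop oracle (no vectorised primitives)
# ---------------------------------------------------------------------------

def _oracle_forward(tokens, wq, wk, wv, theta):
    """Triple-loop attention chain on a [3, d] token matrix."""
    import math

    n, d = len(tokens), len(tokens[0])

    def matmul(a, b):
        rows, inner, cols = len(a), len(b), len(b[0])
        return [[sum(a[i][t] * b[t][j] for t in range(inner))
                 for j in range(cols)] for i in range(rows)]

    q = matmul(tokens, wq)
    k = matmul(tokens, wk)
    v = matmul(tokens, wv)
    g = []
    for i in range(n):
        logits = [sum(q[i][t] * k[j][t] for t in range(d)) / math.sqrt(d)
                  for j in range(n)]
        mx = max(logits)
        exps = [math.exp(l - mx) for l in logits]
        z = sum(exps)
        g.append([e / z for e in exps])
    f = matmul(g, v)
    h = [[theta * v[i][j] + f[i][j] for j in range(d)] for i in range(n)]
    return g, f, h


def _np(x):
    return np.asarray(x, dtype=float)


class TestPoolAndTokens:
    def test_constant_map_pools_to_constant_token(self):
        fmap = np.full((2, 7, 7, 5), 3.25)
        tok = pool_and_tokenize(fmap)
        assert tok.shape == (2, 1, 5)
        np.testing.assert_allclose(tok, 3.25)

    def test_hand_filled_toy_map_means(self):
        fmap = np.arange(8, dtype=float).reshape(1, 2, 2, 2)
        tok = np.asarray(pool_and_tokenize(fmap))
        # channel 0 holds {0,2,4,6}, channel 1 holds {1,3,5,7}
        np.testing.assert_allclose(tok[0, 0], [3.0, 4.0])

    def test_zero_spatial_extent_rejected(self):
        with pytest.raises(ValueError):
            pool_and_tokenize(np.empty((1, 0, 7, 4)))

    def test_assembly_order_and_broadcast(self, rng):
        ta = rng.normal(size=(4, 1, 6))
        tb = rng.normal(size=(4, 1, 6))
        cls = rng.normal(size=6)
        bundle = np.asarray(assemble_tokens(ta, tb, cls))
        assert bundle.shape == (4, 3, 6)
        np.testing.assert_array_equal(bundle[:, 0], ta[:, 0])
        np.testing.assert_array_equal(bundle[:, 1], tb[:, 0])
        for b in range(4):
            np.testing.assert_array_equal(bundle[b, 2], cls)
        # swapping modality tokens permutes rows 0 and 1 only
        swapped = np.asarray(assemble_tokens(tb, ta, cls))
        np.testing.assert_array_equal(swapped[:, 0], bundle[:, 1])
        np.testing.assert_array_equal(swapped[:, 2], bundle[:, 2])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_tokens(rng.normal(size=(1, 1, 4)),
                            rng.normal(size=(1, 1, 5)),
                            rng.normal(size=4))


class TestAttentionEquations:
    def test_zero_projections_give_uniform_attention(self, rng):
        t = rng.normal(size=(2, 3, 4))
        z = np.zeros((2, 3, 4))
        g = np.asarray(attention_matrix(z, z))
        np.testing.assert_allclose(g, 1.0 / 3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        q = r.normal(size=(2, 3, 5))
        k = r.normal(size=(2, 3, 5))
        g = np.asarray(attention_matrix(q, k))
        np.testing.assert_allclose(g.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(g > 0) and np.all(g < 1)

    def test_identity_projection_toy_matches_oracle(self):
        tokens = [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
        eye = np.eye(2)
        g_o, _, _ = _oracle_forward(tokens, eye.tolist(), eye.tolist(),
                                    eye.tolist(), 0.0)
        t = np.asarray(tokens)[None]
        g = np.asarray(attention_matrix(t, t))
        np.testing.assert_allclose(g[0], _np(g_o), atol=1e-12)

    def test_theta_zero_collapses_h_to_f(self, rng):
        g = np.asarray(attention_matrix(rng.normal(size=(1, 3, 4)),
                                        rng.normal(size=(1, 3, 4))))
        v = rng.normal(size=(1, 3, 4))
        f, h = common_features(g, v, 0.0)
        np.testing.assert_array_equal(np.asarray(f), np.asarray(h))

    def test_uniform_attention_of_equal_rows_is_convex_identity(self):
        v_row = np.array([2.0, -1.0, 0.5])
        v = np.tile(v_row, (1, 3, 1))
        g = np.full((1, 3, 3), 1 / 3)
        f, _ = common_features(g, v, 1.0)
        np.testing.assert_allclose(np.asarray(f)[0],
                                   np.tile(v_row, (3, 1)), atol=1e-12)

    def test_toy_matmul_against_loop_oracle(self, rng):
        g = rng.random((1, 3, 3))
        g = g / g.sum(axis=2, keepdims=True)
        v = rng.normal(size=(1, 3, 2))
        theta = 0.7
        f, h = common_features(g, v, theta)
        f_o = [[sum(g[0][i][t] * v[0][t][j] for t in range(3))
                for j in range(2)] for i in range(3)]
        np.testing.assert_allclose(np.asarray(f)[0], _np(f_o), atol=1e-12)
        np.testing.assert_allclose(np.asarray(h)[0],
                                   theta * v[0] + _np(f_o), atol=1e-12)

    def test_negative_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            common_features(np.full((1, 3, 3), 1 / 3),
                            rng.normal(size=(1, 3, 2)), -0.1)


class TestFuse:
    def test_readout_lengths(self, rng):
        g = rng.random((2, 3, 3))
        h = rng.normal(size=(2, 3, 512))
        assert np.asarray(fuse(g, h, "full")).shape == (2, 3 * 512 + 9)
        assert np.asarray(fuse(g, h, "cls")).shape == (2, 512 + 3)
        with pytest.raises(ValueError):
            fuse(g, h, "both")

    def test_zero_tokens_theta_zero_full_readout(self):
        """Zero tokens with zero projections: p = (uniform g flattened,
        zeros)."""
        head = SAFFHead(d=4, theta=0.0)
        params = head.init(np.random.default_rng(0))
        params["wq"][:] = 0; params["wk"][:] = 0; params["wv"][:] = 0
        params["cls"][:] = 0
        out = head.fusion(params, np.zeros((2, 1, 4)), np.zeros((2, 1, 4)))
        p = np.asarray(out.p)
        np.testing.assert_allclose(p[:, :9], 1 / 3, atol=1e-12)
        np.testing.assert_allclose(p[:, 9:], 0.0, atol=1e-12)


class TestClassifier:
    def test_probabilities_sum_to_one(self, rng):
        head = SAFFHead(d=8, hidden=16)
        params = head.init(rng)
        fa = rng.normal(size=(5, 2, 2, 8))
        fb = rng.normal(size=(5, 2, 2, 8))
        probs = np.asarray(head.predict_proba(params, (fa, fb)))
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_weights_give_half_half(self, rng):
        head = SAFFHead(d=4, hidden=8)
        params = head.init(rng)
        params["fc2"]["w"][:] = 0
        params["fc2"]["b"][:] = 0
        probs = np.asarray(head.predict_proba(
            params, (rng.normal(size=(3, 2, 2, 4)),
                     rng.normal(size=(3, 2, 2, 4)))))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_hand_set_final_layer_softmax(self):
        """Length-2 fused vector through a hand-set 2x2 layer: scalar
        softmax arithmetic."""
        head = SAFFHead(d=4, hidden=2)
        params = head.init(np.random.default_rng(0))
        p_vec = np.array([[1.0, 2.0]])          # pretend hidden activations
        logits = p_vec @ np.array([[1.0, 0.0], [0.0, 1.0]])
        expect = np.exp(logits) / np.exp(logits).sum()
        params["fc2"]["w"] = np.eye(2)
        params["fc2"]["b"] = np.zeros(2)
        got = np.asarray(nn.softmax(head.fc2(params["fc2"], p_vec)))
        np.testing.assert_allclose(got, expect, atol=1e-12)


class TestEndToEnd:
    def test_forward_matches_naive_oracle(self, rng):
        """Full SAFF chain on random tokens vs the loop oracle,
        <= 1e-5 relative error."""
        d, theta = 6, 0.9
        head = SAFFHead(d=d, theta=theta)
        params = head.init(rng)
        ta = rng.normal(size=(3, 1, d))
        tb = rng.normal(size=(3, 1, d))
        out = head.fusion(params, ta, tb)
        for b in range(3):
            tokens = np.stack([ta[b, 0], tb[b, 0], params["cls"]])
            g_o, f_o, h_o = _oracle_forward(
                tokens.tolist(), params["wq"].tolist(),
                params["wk"].tolist(), params["wv"].tolist(), theta)
            for got, want in ((out.g[b], g_o), (out.f[b], f_o),
                              (out.h[b], h_o)):
                np.testing.assert_allclose(np.asarray(got), _np(want),
                                           rtol=1e-5, atol=1e-8)

    def test_modality_permutation_equivariance(self, rng):
        """Swapping the two modality tokens permutes rows/cols 0,1 of g and
        rows 0,1 of f."""
        head = SAFFHead(d=5)
        params = head.init(rng)
        ta, tb = rng.normal(size=(2, 1, 5)), rng.normal(size=(2, 1, 5))
        out = head.fusion(params, ta, tb)
        swapped = head.fusion(params, tb, ta)
        perm = [1, 0, 2]
        g_perm = np.asarray(out.g)[:, perm][:, :, perm]
        np.testing.assert_allclose(np.asarray(swapped.g), g_perm, atol=1e-12)
        np.testing.assert_allclose(np.asarray(swapped.f),
                                   np.asarray(out.f)[:, perm], atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        """Autodiff through theta, Wq, Wk, Wv agrees with central finite
        differences to 1e-4."""
        d = 3
        head = SAFFHead(d=d, theta=0.8, theta_learnable=True, hidden=4)
        params = head.init(rng)
        fa = rng.normal(size=(2, 2, 2, d))
        fb = rng.normal(size=(2, 2, 2, d))
        y = np.array([0, 1])

        def loss(p):
            return nn.cross_entropy(head.apply(p, (fa, fb)), y)

        g = grad(loss)(params)
        for key in ("theta", "wq", "wk", "wv", "cls"):
            arr = np.atleast_1d(np.asarray(params[key], dtype=float))
            params[key] = arr if arr.ndim else arr
            garr = np.atleast_1d(np.asarray(g[key]))
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            eps = 1e-6
            arr[idx] += eps
            up = loss(params)
            arr[idx] -= 2 * eps
            down = loss(params)
            arr[idx] += eps
            fd = (up - down) / (2 * eps)
            assert garr[idx] == pytest.approx(fd, abs=1e-4, rel=1e-4), key
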