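"""Edge-convolution operators: oracles, symmetries, gradients."""

import numpy as np
import pytest

from toothseg._autodiff import Tensor
from toothseg.edgeconv import (EdgeConvConfig, LinearTransform, SharedMLP,
                               attention_edge_conv, edge_conv)
from toothseg.errors import ConfigError, ShapeError
from toothseg.neighborhood import NeighborIndex, knn_graph


class _Identity:
    """Identity transform for hand-checkable examples."""

    def __init__(self, dim):
        self.in_dim = self.out_dim = dim

    def __call__(self, x):
        return x

    def parameters(self):
        return []


def _index(rows):
    return NeighborIndex(np.asarray(rows, dtype=np.int64), space_dim=0)


def _loop_edge_conv(x, idx, w, b, variant):
    """Explicit per-face, per-neighbor double loop with a linear map."""
    m = len(x)
    out = None
    for i in range(m):
        vals = []
        for j in idx[i]:
            if variant == "local":
                e = x[j] - x[i]
            elif variant == "global":
                e = x[i]
            else:
                e = np.concatenate([x[i], x[j] - x[i]])
            vals.append(e @ w + b)
        row = np.max(vals, axis=0)
        out = np.zeros((m, len(row))) if out is None else out
        out[i] = row
    return out


def _loop_attention(x, idx, w, b, ws, bs):
    """Loop oracle for attention pooling with per-channel softmax."""
    m, k = idx.shape
    out_dim = w.shape[1]
    out = np.zeros((m, out_dim))
    for i in range(m):
        scores = np.array([np.concatenate([x[i], x[j] - x[i]]) @ ws + bs
                           for j in idx[i]])
        scores -= scores.max(axis=0)
        alpha = np.exp(scores) / np.exp(scores).sum(axis=0)
        feats = np.array([np.concatenate([x[i], x[j]]) @ w + b
                          for j in idx[i]])
        out[i] = (alpha * feats).sum(axis=0)
    return out


class TestEdgeConvVariants:
    def test_combined_hand_example(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0]])
        idx = _index([[1, 2], [0, 2], [0, 1]])
        cfg = EdgeConvConfig(variant="combined", pooling="max", k=2)
        out = edge_conv(x, idx, _Identity(4), cfg)
        # row 0: max over {(1,0,1,0), (1,0,-1,3)} = (1,0,1,3)
        np.testing.assert_allclose(out.data[0], [1, 0, 1, 3])

    def test_local_translation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 5))
        idx = knn_graph(x, 4)
        h = LinearTransform(5, 7, rng=rng)
        cfg = EdgeConvConfig(variant="local", pooling="max", k=4)
        a = edge_conv(x, idx, h, cfg).data
        b = edge_conv(x + 3.7, idx, h, cfg).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("variant", ["global", "local", "combined"])
    def test_matches_loop_oracle(self, variant):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6))
        idx = knn_graph(x, 4)
        d_in = 6 if variant in ("global", "local") else 12
        w = rng.normal(size=(d_in, 5))
        b = rng.normal(size=5)
        h = LinearTransform(d_in, 5, weight=w, bias=b)
        cfg = EdgeConvConfig(variant=variant, pooling="max", k=4)
        out = edge_conv(x, idx, h, cfg).data
        np.testing.assert_allclose(
            out, _loop_edge_conv(x, idx.indices, w, b, variant), atol=1e-10)

    def test_dilated_reduces_to_combined_when_full(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 4))
        idx = knn_graph(x, 5)
        h = LinearTransform(8, 6, rng=rng)
        a = edge_conv(x, idx, h,
                      EdgeConvConfig("combined", "max", 5)).data
        b = edge_conv(x, idx, h, EdgeConvConfig("dilated", "max", 5)).data
        np.testing.assert_array_equal(a, b)

    def test_dimension_mismatch_names_variant(self):
        x = np.zeros((5, 3))
        idx = _index([[1], [2], [3], [4], [0]])
        with pytest.raises(ShapeError, match="combined"):
            edge_conv(x, idx, _Identity(3),
                      EdgeConvConfig("combined", "max", 1))

    def test_attention_config_forbids_max(self):
        with pytest.raises(ConfigError):
            EdgeConvConfig(variant="attention", pooling="max", k=4)


class TestAttentionEdgeConv:
    def test_constant_scores_give_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 3))
        idx = knn_graph(x, 4)
        h = LinearTransform(6, 4, rng=rng)
        h_sigma = LinearTransform(6, 4,
                                  weight=np.zeros((6, 4)),
                                  bias=np.zeros(4))
        out = attention_edge_conv(x, idx, h, h_sigma).data
        # alpha uniform -> mean over neighbors of h(x_i || x_j)
        expect = np.zeros_like(out)
        for i in range(15):
            feats = [np.concatenate([x[i], x[j]]) @ h.weight.data
                     + h.bias.data for j in idx.indices[i]]
            expect[i] = np.mean(feats, axis=0)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_single_neighbor_softmax_is_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        idx = _index([[1], [2], [3], [4], [5], [0]])
        h = LinearTransform(6, 5, rng=rng)
        h_sigma = LinearTransform(6, 5, rng=rng)
        out = attention_edge_conv(x, idx, h, h_sigma).data
        for i in range(6):
            j = idx.indices[i, 0]
            expect = np.concatenate([x[i], x[j]]) @ h.weight.data \
                + h.bias.data
            np.testing.assert_allclose(out[i], expect, atol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 4))
        idx = knn_graph(x, 5)
        w, b = rng.normal(size=(8, 6)), rng.normal(size=6)
        ws, bs = rng.normal(size=(8, 6)), rng.normal(size=6)
        out = attention_edge_conv(
            x, idx, LinearTransform(8, 6, weight=w, bias=b),
            LinearTransform(8, 6, weight=ws, bias=bs)).data
        np.testing.assert_allclose(
            out, _loop_attention(x, idx.indices, w, b, ws, bs), atol=1e-9)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 3))
        idx = knn_graph(x, 6)
        scores = Tensor(rng.normal(size=(20, 6, 4)))
        alpha = scores.softmax(axis=1)
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)


class TestSymmetries:
    @pytest.mark.parametrize("variant", ["local", "combined"])
    def test_permutation_equivariance(self, variant):
        rng = np.random.default_rng(7)
        m = 25
        x = rng.normal(size=(m, 4))
        idx = knn_graph(x, 5)
        d_in = 4 if variant == "local" else 8
        h = LinearTransform(d_in, 6, rng=rng)
        cfg = EdgeConvConfig(variant, "max", 5)
        base = edge_conv(x, idx, h, cfg).data
        perm = rng.permutation(m)
        inv = np.empty(m, dtype=int)
        inv[perm] = np.arange(m)
        idx_p = NeighborIndex(inv[idx.indices][perm], space_dim=4)
        out = edge_conv(x[perm], idx_p, h, cfg).data
        np.testing.assert_allclose(out, base[perm], atol=1e-12)

    def test_neighbor_order_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 4))
        idx = knn_graph(x, 6)
        shuffled = idx.indices.copy()
        for row in shuffled:
            rng.shuffle(row)
        h = LinearTransform(8, 5, rng=rng)
        hs = LinearTransform(8, 5, rng=rng)
        cfg = EdgeConvConfig("combined", "max", 6)
        a = edge_conv(x, idx, h, cfg).data
        b = edge_conv(x, NeighborIndex(shuffled, 4), h, cfg).data
        np.testing.assert_array_equal(a, b)
        aa = attention_edge_conv(x, idx, h, hs).data
        bb = attention_edge_conv(x, NeighborIndex(shuffled, 4), h, hs).data
        np.testing.assert_allclose(aa, bb, atol=1e-12)

    def test_max_pool_monotone_under_superset(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 4))
        small = knn_graph(x, 3)
        big = knn_graph(x, 7)  # superset rows of the k=3 graph
        h = LinearTransform(8, 5, rng=rng)
        cfg3 = EdgeConvConfig("combined", "max", 3)
        cfg7 = EdgeConvConfig("combined", "max", 7)
        a = edge_conv(x, small, h, cfg3).data
        b = edge_conv(x, big, h, cfg7).data
        assert np.all(b >= a - 1e-12)


class TestGradients:
    """Analytic gradients vs central finite differences."""

    @staticmethod
    def _num_grad(fn, arr, eps=1e-6):
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gf = g.ravel()
        for i in range(arr.size):
            old = flat[i]
            flat[i] = old + eps
            hi = fn()
            flat[i] = old - eps
            lo = fn()
            flat[i] = old
            gf[i] = (hi - lo) / (2 * eps)
        return g

    @pytest.mark.parametrize("variant", ["local", "combined", "dilated"])
    def test_edge_conv_input_gradient(self, variant):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(8, 3))
        idx = knn_graph(x.copy(), 3)
        d_in = 3 if variant == "local" else 6
        h = LinearTransform(d_in, 4, rng=rng)
        proj = rng.normal(size=(8, 4))
        cfg = EdgeConvConfig(variant, "max", 3)

        def value():
            return float((edge_conv(x, idx, h, cfg).data * proj).sum())

        xt = Tensor(x, requires_grad=True)
        out = edge_conv(xt, idx, h, cfg)
        (out * Tensor(proj)).sum().backward()
        np.testing.assert_allclose(xt.grad, self._num_grad(value, x),
                                   atol=1e-4)

    def test_attention_gradient(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(7, 3))
        idx = knn_graph(x.copy(), 3)
        h = LinearTransform(6, 4, rng=rng)
        hs = LinearTransform(6, 4, rng=rng)
        proj = rng.normal(size=(7, 4))

        def value():
            return float((attention_edge_conv(x, idx, h, hs).data
                          * proj).sum())

        xt = Tensor(x, requires_grad=True)
        (attention_edge_conv(xt, idx, h, hs) * Tensor(proj)).sum().backward()
        np.testing.assert_allclose(xt.grad, self._num_grad(value, x),
                                   atol=1e-4)

    def test_shared_mlp_parameter_gradients(self):
        rng = np.random.default_rng(12)
        mlp = SharedMLP([3, 5, 4], rng)
        x = rng.normal(size=(6, 3))
        proj = rng.normal(size=(6, 4))

        def value():
            return float((mlp(Tensor(x)).data * proj).sum())

        out = mlp(Tensor(x))
        (out * Tensor(proj)).sum().backward()
        for p in mlp.parameters():
            np.testing.assert_allclose(p.grad,
                                       self._num_grad(value, p.data),
                                       atol=1e-4)

    def test_cross_entropy_gradient(self):
        rng = np.random.default_rng(13)
        logits = rng.normal(size=(6, 4))
        labels = rng.integers(0, 4, size=6)

        def value():
            return float(Tensor(logits).cross_entropy(labels).data)

        t = Tensor(logits, requires_grad=True)
        t.cross_entropy(labels).backward()
        np.testing.assert_allclose(t.grad, self._num_grad(value, logits),
                                   atol=1e-6)
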