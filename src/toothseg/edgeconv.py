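"""Edge-convolution operators over a neighbor index.

For a face x_i with neighbors x_j, an edge convolution applies a shared
learnable map h to per-edge features and pools symmetrically over the
neighborhood.  Five variants are provided:

* ``global``    — pool_j h(x_i): only the face's own feature (under max
  pooling this reduces to h(x_i)); kept for ablations.
* ``local``     — pool_j h(x_j − x_i): translation-invariant
  neighborhood differences.
* ``combined``  — pool_j h(x_i ‖ x_j − x_i): the default operator,
  carrying both the face's own feature and its local context.
* ``dilated``   — the combined form max-pooled over a farthest-point
  sampled neighborhood N_s(i), widening the receptive field at fixed
  edge count.
* attention     — h-features weighted by per-channel softmax attention
  scores from a second lightweight MLP h_σ and sum-pooled
  (:func:`attention_edge_conv`).  The attention scores see
  (x_i ‖ x_j − x_i); the pooled features see (x_i ‖ x_j), as printed in
  the construction this follows (a difference-form variant is available
  via ``use_difference``).

All operators are pure functions of (features, index, parameters),
permutation-equivariant over faces and invariant to neighbor order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, edge_features, layer_norm, linear
from .errors import ConfigError, ShapeError
from .neighborhood import NeighborIndex

__all__ = ["LearnableTransform", "LinearTransform", "SharedMLP",
           "EdgeConvConfig", "edge_conv", "attention_edge_conv"]

VARIANTS = ("global", "local", "combined", "attention", "dilated")


class LearnableTransform:
    """A shared differentiable map applied identically to every row of an
    E×in_dim batch."""

    in_dim: int
    out_dim: int

    def __call__(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self) -> list[Tensor]:  # pragma: no cover - interface
        raise NotImplementedError


class LinearTransform(LearnableTransform):
    """Affine map W x + b (He-initialized)."""

    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None,
                 weight: np.ndarray | None = None,
                 bias: np.ndarray | None = None):
        self.in_dim, self.out_dim = in_dim, out_dim
        if weight is None:
            rng = rng or np.random.default_rng(0)
            weight = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                                (in_dim, out_dim))
        if bias is None:
            bias = np.zeros(out_dim)
        self.weight = Tensor(weight, requires_grad=True)
        self.bias = Tensor(bias, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class _LayerNorm:
    """Per-row normalization over channels with learned gain and bias.

    Normalizing per face (rather than over the batch of faces) keeps
    every face's output a function of that face's inputs alone, which
    preserves the locality of the receptive field.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class SharedMLP(LearnableTransform):
    """Stack of (linear → layer norm → leaky ReLU) blocks."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 slope: float = 0.2, final_activation: bool = True):
        if len(dims) < 2:
            raise ConfigError("SharedMLP needs at least in and out dims")
        self.in_dim, self.out_dim = dims[0], dims[-1]
        self.slope = slope
        self.blocks: list[tuple[LinearTransform, _LayerNorm | None]] = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            lin = LinearTransform(a, b, rng=rng)
            norm = _LayerNorm(b) if (final_activation or not last) else None
            self.blocks.append((lin, norm))
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.blocks)
        for i, (lin, norm) in enumerate(self.blocks):
            x = lin(x)
            if norm is not None:
                x = norm(x)
            if i < n - 1 or self.final_activation:
                x = x.leaky_relu(self.slope)
        return x

    def parameters(self) -> list[Tensor]:
        out = []
        for lin, norm in self.blocks:
            out.extend(lin.parameters())
            if norm is not None:
                out.extend(norm.parameters())
        return out


@dataclass
class EdgeConvConfig:
    """Variant, pooling, and neighborhood width of one edge convolution."""

    variant: str = "combined"
    pooling: str = "max"
    k: int = 32

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.pooling not in ("max", "attention"):
            raise ConfigError(f"unknown pooling {self.pooling!r}")
        if self.variant == "attention" and self.pooling == "max":
            raise ConfigError(
                "the attention variant defines its own weighted sum; "
                "pooling='max' is not applicable")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _apply_shared(h: LearnableTransform, e: Tensor) -> Tensor:
    """Apply a shared transform to an (M, k, d) edge tensor."""
    m, k, d = e.shape
    return h(e.reshape(m * k, d)).reshape(m, k, h.out_dim)


def edge_conv(features, neighbors: NeighborIndex, h: LearnableTransform,
              config: EdgeConvConfig) -> Tensor:
    """Apply one edge-convolution variant (global/local/combined/dilated)
    with max pooling over the neighbor rows."""
    x = _as_tensor(features)
    m, d = x.shape
    idx = neighbors.indices
    if idx.shape[0] != m:
        raise ShapeError(
            f"{config.variant}: neighbor index has {idx.shape[0]} rows "
            f"for {m} faces")
    expect = d if config.variant in ("global", "local") else 2 * d
    if h.in_dim != expect:
        raise ShapeError(
            f"{config.variant}: transform expects in_dim={h.in_dim}, "
            f"edge features have {expect}")
    if config.variant == "attention":
        raise ConfigError("use attention_edge_conv for the attention "
                          "variant")
    if config.pooling != "max":
        raise ConfigError(f"{config.variant} supports only max pooling")

    if config.variant == "global":
        # pool_j h(x_i) over a j-independent term: max of identical rows
        return h(x)
    mode = "diff" if config.variant == "local" else "concat_diff"
    # combined and dilated share the (x_i ‖ x_j − x_i) edge feature
    e = edge_features(x, idx, mode)
    return _apply_shared(h, e).max(axis=1)


def attention_edge_conv(features, neighbors: NeighborIndex,
                        h: LearnableTransform,
                        h_sigma: LearnableTransform,
                        use_difference: bool = False) -> Tensor:
    """Attention-pooled edge convolution.

    Per-channel attention weights are the softmax over the k neighbors of
    scores h_σ(x_i ‖ x_j − x_i); the output is the attention-weighted sum
    of h(x_i ‖ x_j) (or h(x_i ‖ x_j − x_i) when ``use_difference``).
    """
    x = _as_tensor(features)
    m, d = x.shape
    if h.in_dim != 2 * d or h_sigma.in_dim != 2 * d:
        raise ShapeError(
            f"attention: transforms expect in_dim 2d={2 * d}, got "
            f"h={h.in_dim}, h_sigma={h_sigma.in_dim}")
    if h_sigma.out_dim != h.out_dim:
        raise ShapeError("attention: h_sigma.out_dim must equal h.out_dim")
    idx = neighbors.indices
    scores = _apply_shared(h_sigma, edge_features(x, idx, "concat_diff"))
    alpha = scores.softmax(axis=1)
    feat_in = edge_features(
        x, idx, "concat_diff" if use_difference else "concat_raw")
    e = _apply_shared(h, feat_in)
    return (alpha * e).sum(axis=1)
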