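"""The segmentation network: local block → dilated block → head.

The local feature-learning block stacks edge convolutions on a kNN graph
that is either *dynamic* (recomputed in the learned feature space before
every layer) or *static* (built once from the input features).  The
dilated block stacks dilated edge convolutions whose farthest-point
sampled neighborhoods come from progressively larger nearest-neighbor
sets of the face centers; those indices depend only on the mesh
geometry, so they can be precomputed and reused.  The prediction head is
a point-wise MLP over the concatenation of every block output plus a
globally max-pooled context vector, emitting one logit row per face.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, default_dtype, guided_gradients
from .edgeconv import (EdgeConvConfig, LinearTransform, SharedMLP,
                      attention_edge_conv, edge_conv)
from .errors import ConfigError, ParameterError, ShapeError, VersionError
from .mesh_io import FaceFeatureMatrix
from .neighborhood import NeighborIndex, dilated_neighborhood, knn_graph

__all__ = ["NetworkConfig", "SegmentationResult", "SegmentationModel",
           "build_network", "forward", "guided_backprop_salience",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults follow the published configuration where one is printed
    (17 classes, dilated sample sizes 200/600/1800, single stream with
    max pooling on a dynamic graph); layer counts and widths are
    inferred defaults, kept here so no constant is buried in code.
    """

    in_dim: int = 24
    n_local_layers: int = 3
    local_k: int = 32
    local_widths: list[int] = field(default_factory=lambda: [64, 64, 128])
    dilated_kb_list: list[int] = field(
        default_factory=lambda: [200, 600, 1800])
    dilated_f: int = 32
    dilated_width: int = 256
    head_widths: list[int] = field(default_factory=lambda: [512, 256, 128])
    n_classes: int = 17
    graph_mode: str = "dynamic"
    pooling: str = "max"
    split_streams: bool = False
    global_context: bool = True
    dropout: float = 0.0
    precision: str = "float64"
    seed: int = 0

    def __post_init__(self):
        if len(self.local_widths) != self.n_local_layers:
            raise ConfigError(
                f"n_local_layers={self.n_local_layers} but "
                f"{len(self.local_widths)} local widths")
        if self.dilated_kb_list:
            if any(b >= a for a, b in zip(self.dilated_kb_list[1:],
                                          self.dilated_kb_list[:-1])):
                raise ConfigError("dilated_kb_list must be strictly "
                                  "increasing")
            if self.dilated_f > min(self.dilated_kb_list):
                raise ConfigError("dilated_f must not exceed the smallest "
                                  "k_b")
        if self.graph_mode not in ("dynamic", "static"):
            raise ConfigError(f"unknown graph_mode {self.graph_mode!r}")
        if self.pooling not in ("max", "attention"):
            raise ConfigError(f"unknown pooling {self.pooling!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.precision not in ("float64", "float32"):
            raise ConfigError(f"unknown precision {self.precision!r}")
        if self.split_streams and self.in_dim % 2:
            raise ConfigError("split_streams needs an even in_dim")


@dataclass
class SegmentationResult:
    """Per-face class probabilities, argmax labels, and raw logits."""

    probabilities: np.ndarray
    labels: np.ndarray
    logits: np.ndarray

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "SegmentationResult":
        logits = np.asarray(logits, dtype=np.float64)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        return cls(probabilities=probs, labels=np.argmax(probs, axis=1),
                   logits=logits)


class _LocalLayer:
    """One edge convolution of the local block (one per stream)."""

    def __init__(self, in_dim: int, width: int, pooling: str,
                 rng: np.random.Generator):
        self.pooling = pooling
        self.h = SharedMLP([2 * in_dim, width], rng)
        self.h_sigma = (SharedMLP([2 * in_dim, width], rng,
                                  final_activation=False)
                        if pooling == "attention" else None)
        self.out_dim = width

    def __call__(self, x: Tensor, index: NeighborIndex) -> Tensor:
        if self.pooling == "attention":
            return attention_edge_conv(x, index, self.h, self.h_sigma)
        cfg = EdgeConvConfig(variant="combined", pooling="max",
                             k=index.k)
        return edge_conv(x, index, self.h, cfg)

    def parameters(self) -> list[Tensor]:
        out = self.h.parameters()
        if self.h_sigma is not None:
            out += self.h_sigma.parameters()
        return out


class SegmentationModel:
    """Parameterized network; build with :func:`build_network`."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1]))
        with default_dtype(config.precision):
            self._build(config, rng)

    def _build(self, config: NetworkConfig, rng: np.random.Generator):
        n_streams = 2 if config.split_streams else 1
        stream_in = config.in_dim // n_streams
        self.local: list[list[_LocalLayer]] = []
        for _ in range(n_streams):
            layers, d = [], stream_in
            for w in config.local_widths:
                layers.append(_LocalLayer(d, w, config.pooling, rng))
                d = w
            self.local.append(layers)
        local_out = (config.local_widths[-1] * n_streams
                     if config.local_widths else config.in_dim)

        self.dilated: list[SharedMLP] = []
        d = local_out
        for _ in config.dilated_kb_list:
            self.dilated.append(SharedMLP([2 * d, config.dilated_width],
                                          rng))
            d = config.dilated_width

        concat_dim = (sum(config.local_widths) * n_streams
                      + len(config.dilated_kb_list) * config.dilated_width)
        head_in = concat_dim * (2 if config.global_context else 1)
        self.head = SharedMLP([head_in] + list(config.head_widths), rng)
        self.classifier = LinearTransform(config.head_widths[-1],
                                          config.n_classes, rng=rng)

    # -- plumbing --------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for stream in self.local:
            for layer in stream:
                out += layer.parameters()
        for h in self.dilated:
            out += h.parameters()
        out += self.head.parameters()
        out += self.classifier.parameters()
        return out

    def compute_dilated_indices(self, centers: np.ndarray
                                ) -> list[NeighborIndex]:
        """The static FPS neighborhoods, one per configured k_b."""
        return [dilated_neighborhood(centers, k_b, self.config.dilated_f)
                for k_b in self.config.dilated_kb_list]

    # -- forward ---------------------------------------------------------

    def forward_tensors(self, x: Tensor,
                        dilated_indices: list[NeighborIndex],
                        training: bool = False,
                        input_graph: NeighborIndex | None = None) -> Tensor:
        """Logits as a differentiable tensor.

        ``input_graph`` optionally supplies the kNN graph of the input
        features (it is a pure function of them, so callers that run
        many passes over one mesh can compute it once).
        """
        with default_dtype(self.config.precision):
            return self._forward(x, dilated_indices, training, input_graph)

    def _forward(self, x: Tensor, dilated_indices: list[NeighborIndex],
                 training: bool,
                 input_graph: NeighborIndex | None = None) -> Tensor:
        cfg = self.config
        m = x.shape[0]
        if x.shape[1] != cfg.in_dim:
            raise ShapeError(f"expected {cfg.in_dim} feature columns, got "
                             f"{x.shape[1]}")
        if len(dilated_indices) != len(cfg.dilated_kb_list):
            raise ShapeError(
                f"expected {len(cfg.dilated_kb_list)} dilated indices, "
                f"got {len(dilated_indices)}")
        if cfg.local_widths and cfg.local_k >= m:
            raise ShapeError(f"local_k={cfg.local_k} needs more than "
                             f"{m} faces")

        if cfg.split_streams:
            half = cfg.in_dim // 2
            streams = [x.slice_cols(0, half), x.slice_cols(half, cfg.in_dim)]
        else:
            streams = [x]

        cacheable = input_graph is not None and not cfg.split_streams
        outs: list[Tensor] = []
        last_per_stream: list[Tensor] = []
        for stream_x, layers in zip(streams, self.local):
            cur = stream_x
            static_index = None
            if cfg.graph_mode == "static" and layers:
                static_index = (input_graph if cacheable
                                else knn_graph(cur.data, cfg.local_k))
            for li, layer in enumerate(layers):
                if cfg.graph_mode == "static":
                    index = static_index
                elif li == 0 and cacheable:
                    index = input_graph
                else:
                    index = knn_graph(cur.data, cfg.local_k)
                cur = layer(cur, index)
                outs.append(cur)
            last_per_stream.append(cur)

        cur = (concat(last_per_stream, axis=-1)
               if len(last_per_stream) > 1 else last_per_stream[0])
        for h, index in zip(self.dilated, dilated_indices):
            cfg_d = EdgeConvConfig(variant="dilated", pooling="max",
                                   k=index.k)
            cur = edge_conv(cur, index, h, cfg_d)
            outs.append(cur)

        feats = concat(outs, axis=-1) if len(outs) > 1 else outs[0]
        if cfg.global_context:
            g = feats.max(axis=0)                       # (D,)
            g_rows = g.reshape(1, -1) * Tensor(np.ones((m, 1)))
            feats = concat([feats, g_rows], axis=-1)
        hidden = self.head(feats)
        if training and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            mask = (self._drop_rng.random(hidden.shape) < keep) / keep
            hidden = hidden * Tensor(mask)
        return self.classifier(hidden)


def build_network(config: NetworkConfig) -> SegmentationModel:
    """Instantiate the network with seeded parameter initialization."""
    return SegmentationModel(config)


def _validated_indices(model: SegmentationModel,
                       features: FaceFeatureMatrix,
                       precomputed: list[NeighborIndex] | None
                       ) -> list[NeighborIndex]:
    cfg = model.config
    if precomputed is None:
        return model.compute_dilated_indices(features.centers)
    for idx, k_b in zip(precomputed, cfg.dilated_kb_list):
        if (not idx.dilated or idx.source_k != k_b
                or idx.k != cfg.dilated_f
                or idx.n_points != features.n_faces):
            raise ShapeError(
                "precomputed dilated index does not match the configured "
                f"(k_b={k_b}, f={cfg.dilated_f}) for this mesh")
    return precomputed


def forward(model: SegmentationModel, features: FaceFeatureMatrix,
            precomputed_dilated: list[NeighborIndex] | None = None
            ) -> SegmentationResult:
    """Run inference on one mesh.

    When ``precomputed_dilated`` is absent the static indices are
    computed from the feature matrix's center columns on the fly; both
    paths produce bit-identical results.
    """
    indices = _validated_indices(model, features, precomputed_dilated)
    logits = model.forward_tensors(Tensor(features.values), indices,
                                   training=False)
    return SegmentationResult.from_logits(logits.data)


def guided_backprop_salience(model: SegmentationModel,
                             features: FaceFeatureMatrix,
                             target_class: int,
                             precomputed_dilated: list[NeighborIndex]
                             | None = None) -> np.ndarray:
    """Per-face salience for one class via guided backpropagation.

    The summed target-class logit is backpropagated to the input rows
    with negative gradients suppressed at every rectification; the
    salience of a face is the Euclidean norm of its input-row gradient.
    """
    cfg = model.config
    if not 0 <= target_class < cfg.n_classes:
        raise ParameterError(f"target_class {target_class} outside "
                             f"0..{cfg.n_classes - 1}")
    indices = _validated_indices(model, features, precomputed_dilated)
    x = Tensor(features.values, requires_grad=True)
    logits = model.forward_tensors(x, indices, training=False)
    onehot = np.zeros(cfg.n_classes)
    onehot[target_class] = 1.0
    score = (logits * Tensor(onehot)).sum()
    with guided_gradients():
        score.backward()
    return np.linalg.norm(x.grad, axis=1)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SegmentationModel, path) -> None:
    """Single-file archive of config + parameters + format version."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, __version__=CHECKPOINT_VERSION,
             config=np.array(json.dumps(asdict(model.config))), **arrays)


def load_checkpoint(path, expect_config: NetworkConfig | None = None
                    ) -> SegmentationModel:
    """Rebuild a model from a checkpoint; refuses config mismatches."""
    with np.load(path) as z:
        if int(z["__version__"]) != CHECKPOINT_VERSION:
            raise VersionError(
                f"checkpoint format {int(z['__version__'])} unsupported")
        config = NetworkConfig(**json.loads(str(z["config"])))
        if expect_config is not None and config != expect_config:
            raise VersionError("checkpoint config does not match the "
                               "requested configuration")
        model = build_network(config)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = z[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise VersionError("checkpoint parameter shapes do not "
                                   "match the configuration")
            p.data = stored.astype(p.data.dtype)
    return model
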