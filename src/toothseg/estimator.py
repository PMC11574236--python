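"""Scikit-learn-style estimator wrapping the full pipeline.

:class:`DilatedEdgeConvSegmenter` is the primary user-facing surface:
construct with hyperparameters, ``fit`` on a list of meshes (or
precomputed feature matrices) with per-face labels, then ``predict`` or
``predict_proba`` on new meshes.  It composes with scikit-learn
``get_params``/``set_params``/``clone`` semantics; the functional API in
:mod:`toothseg.network` and :mod:`toothseg.train_eval` stays available
underneath.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DataError
from .mesh_io import (FaceFeatureMatrix, TriMesh, compute_face_features,
                      zscore_normalize)
from .network import NetworkConfig, build_network, forward, \
    guided_backprop_salience
from .train_eval import TrainConfig, evaluate, train

__all__ = ["DilatedEdgeConvSegmenter"]


class DilatedEdgeConvSegmenter(BaseEstimator):
    """Per-face mesh segmenter with dynamic and dilated edge convolution.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainConfig`;
    defaults are the full-size dental configuration.  ``fit`` expects
    ``X`` as a list of :class:`TriMesh` or :class:`FaceFeatureMatrix`
    and ``y`` as a list of per-face label arrays (``y=None`` is allowed
    when the meshes carry labels).

    Attributes set by ``fit``: ``model_`` (the trained network),
    ``log_`` (per-step loss records), ``classes_``,
    ``n_features_in_``.
    """

    def __init__(self, *, local_widths=(64, 64, 128), local_k=32,
                 dilated_kb_list=(200, 600, 1800), dilated_f=32,
                 dilated_width=256, head_widths=(512, 256, 128),
                 n_classes=17, graph_mode="dynamic", pooling="max",
                 split_streams=False, global_context=True, dropout=0.0,
                 precision="float64", epochs=100, lr=1e-3, lr_decay=0.5,
                 lr_step_epochs=30, batch_size=4, max_steps=None,
                 random_state=0):
        self.local_widths = local_widths
        self.local_k = local_k
        self.dilated_kb_list = dilated_kb_list
        self.dilated_f = dilated_f
        self.dilated_width = dilated_width
        self.head_widths = head_widths
        self.n_classes = n_classes
        self.graph_mode = graph_mode
        self.pooling = pooling
        self.split_streams = split_streams
        self.global_context = global_context
        self.dropout = dropout
        self.precision = precision
        self.epochs = epochs
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_step_epochs = lr_step_epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.random_state = random_state

    # -- config assembly -------------------------------------------------

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            n_local_layers=len(self.local_widths),
            local_k=self.local_k,
            local_widths=list(self.local_widths),
            dilated_kb_list=list(self.dilated_kb_list),
            dilated_f=self.dilated_f,
            dilated_width=self.dilated_width,
            head_widths=list(self.head_widths),
            n_classes=self.n_classes,
            graph_mode=self.graph_mode,
            pooling=self.pooling,
            split_streams=self.split_streams,
            global_context=self.global_context,
            dropout=self.dropout,
            precision=self.precision,
            seed=self.random_state,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, lr=self.lr,
                           lr_decay=self.lr_decay,
                           lr_step_epochs=self.lr_step_epochs,
                           batch_size=self.batch_size,
                           max_steps=self.max_steps,
                           seed=self.random_state)

    @staticmethod
    def _features(item) -> FaceFeatureMatrix:
        if isinstance(item, FaceFeatureMatrix):
            return (item if item.normalized
                    else zscore_normalize(item))
        if isinstance(item, TriMesh):
            return zscore_normalize(compute_face_features(item))
        raise DataError(f"cannot interpret {type(item).__name__} as a mesh")

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None):
        if y is None:
            y = []
            for item in X:
                if not isinstance(item, TriMesh) or item.face_labels is None:
                    raise DataError("y=None requires labeled TriMesh inputs")
                y.append(item.face_labels)
        if len(X) != len(y):
            raise DataError("X and y differ in length")
        dataset = [(self._features(item), np.asarray(labels))
                   for item, labels in zip(X, y)]
        model = build_network(self.network_config())
        model, log = train(model, dataset, self.train_config())
        self.model_ = model
        self.log_ = log
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = model.config.in_dim
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise DataError("estimator is not fitted; call fit first")

    def predict_proba(self, X) -> list[np.ndarray]:
        self._check_fitted()
        return [forward(self.model_, self._features(item)).probabilities
                for item in X]

    def predict(self, X) -> list[np.ndarray]:
        self._check_fitted()
        return [forward(self.model_, self._features(item)).labels
                for item in X]

    def score(self, X, y) -> float:
        """Pooled per-face accuracy over all meshes."""
        preds = self.predict(X)
        pooled_pred = np.concatenate(preds)
        pooled_true = np.concatenate([np.asarray(t) for t in y])
        report = evaluate(pooled_pred, pooled_true,
                          class_count=self.n_classes)
        return report.overall_accuracy

    def salience(self, item, target_class: int) -> np.ndarray:
        """Guided-backpropagation salience for one mesh and class."""
        self._check_fitted()
        return guided_backprop_salience(self.model_, self._features(item),
                                        target_class)
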