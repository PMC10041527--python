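"""Scikit-learn-style estimator wrapping the two-tailed network.

``EpigenomeNet`` follows the sklearn estimator contract: all hyperparameters
are constructor arguments stored verbatim, state learned from data lives in
trailing-underscore attributes set by :meth:`fit`, and ``get_params`` /
``set_params`` come from :class:`sklearn.base.BaseEstimator`, so the model
composes with sklearn model-selection utilities.

X is an array of one-hot sequence windows with shape
``(n_samples, 4, window)``; y is the sparse target tensor
``(n_samples, n_cells, n_features)`` with NaN at unmeasured entries, and the
boolean measurement mask is passed to ``fit`` alongside y.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._autograd import Tensor
from .model import DEFAULT_CONV_SPEC, ModelConfig, Network
from .training import LossSpec, TrainConfig, train
from .tracks import Sample, encode_sequence


def samples_to_arrays(samples: list) -> tuple:
    """Stack a list of Samples into (X, y, mask) arrays for the estimator."""
    X = np.stack([encode_sequence(s.sequence_window) for s in samples])
    y = np.stack([s.targets for s in samples])
    mask = np.stack([s.measured_mask for s in samples])
    return X, y, mask


class EpigenomeNet(BaseEstimator):
    """Cell-state-aware epigenetic track predictor.

    Parameters
    ----------
    task : 'qualitative' predicts peak-presence probabilities with a
        logistic output and masked binary cross-entropy; 'quantitative'
        regresses the transformed signal with masked MSE.
    head_variant : 'single' predicts targets directly; 'split_MD' (requires
        the quantitative task) predicts the across-cell mean profile M and
        cell-specific deviations D with loss a*MSE(M) + (1-a)*MSE(D).
    emb_length : dimension of the learned cell-type embedding.
    conv_spec : (channels, kernel, pool) triples of the sequence tail.
    a_weight : weight of the mean-profile term in the split loss.
    """

    def __init__(
        self,
        task: str = "qualitative",
        head_variant: str = "single",
        emb_length: int = 32,
        seq_embedding_size: int | None = None,
        conv_spec: tuple = DEFAULT_CONV_SPEC,
        head_depth: int = 8,
        head_width: int = 512,
        a_weight: float = 0.0002,
        epochs: int = 20,
        initial_lr: float = 0.0001,
        batch_size: int = 16,
        emb_weight_decay: float = 1.0,
        weight_decay: float = 0.0,
        input_length: int = 1000,
        seed: int = 0,
    ):
        self.task = task
        self.head_variant = head_variant
        self.emb_length = emb_length
        self.seq_embedding_size = seq_embedding_size
        self.conv_spec = conv_spec
        self.head_depth = head_depth
        self.head_width = head_width
        self.a_weight = a_weight
        self.epochs = epochs
        self.initial_lr = initial_lr
        self.batch_size = batch_size
        self.emb_weight_decay = emb_weight_decay
        self.weight_decay = weight_decay
        self.input_length = input_length
        self.seed = seed

    # ------------------------------------------------------------------

    def _model_config(self, n_cells: int, n_features: int) -> ModelConfig:
        return ModelConfig(
            n_cells=n_cells,
            n_features=n_features,
            emb_length=self.emb_length,
            seq_embedding_size=self.seq_embedding_size,
            head_depth=self.head_depth,
            head_width=self.head_width,
            head_variant=self.head_variant,
            task=self.task,
            conv_spec=tuple(tuple(t) for t in self.conv_spec),
            input_length=self.input_length,
            seed=self.seed,
        )

    def fit(self, X, y, mask=None, X_val=None, y_val=None, mask_val=None, log=None):
        """Fit the network on sparse targets.

        Parameters
        ----------
        X : (n_samples, 4, window) one-hot sequences.
        y : (n_samples, n_cells, n_features) targets, NaN where unmeasured.
        mask : boolean array like y; defaults to ~isnan(y).
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 3 or X.shape[1] != 4:
            raise ValueError("X must have shape (n_samples, 4, window)")
        if y.ndim != 3 or y.shape[0] != X.shape[0]:
            raise ValueError("y must have shape (n_samples, n_cells, n_features)")
        if mask is None:
            mask = ~np.isnan(y)
        mask = np.asarray(mask, bool)
        self.n_cells_ = y.shape[1]
        self.n_features_ = y.shape[2]
        self.net_ = Network(self._model_config(self.n_cells_, self.n_features_))
        loss_spec = LossSpec(task=self.task, a_weight=self.a_weight)
        cfg = TrainConfig(
            epochs=self.epochs,
            initial_lr=self.initial_lr,
            batch_size=self.batch_size,
            emb_weight_decay=self.emb_weight_decay,
            weight_decay=self.weight_decay,
            seed=self.seed,
        )
        _, self.history_ = train(
            self.net_, X, y, mask, loss_spec, cfg,
            X_val=X_val, y_val=y_val, mask_val=mask_val, log=log,
        )
        self.embedding_ = self.net_.get_cell_embeddings()
        return self

    # ------------------------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "net_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def predict(self, X, cells=None, batch_size: int = 64) -> np.ndarray:
        """Combined predictions (n_samples, |cells|, n_features)."""
        self._require_fitted()
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X[None]
        out = []
        for start in range(0, X.shape[0], batch_size):
            out.append(self.net_.forward(Tensor(X[start : start + batch_size]), cells).data)
        return np.concatenate(out, axis=0)

    def predict_split(self, X, cells=None, batch_size: int = 64) -> tuple:
        """(M, D, combined) from the split head."""
        self._require_fitted()
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X[None]
        ms, ds = [], []
        for start in range(0, X.shape[0], batch_size):
            m, d = self.net_.forward_split(Tensor(X[start : start + batch_size]), cells)
            ms.append(m.data)
            ds.append(d.data)
        M = np.concatenate(ms, axis=0)
        D = np.concatenate(ds, axis=0)
        return M, D, M[:, None, :] + D

    def predict_proba(self, X, cells=None) -> np.ndarray:
        if self.task != "qualitative":
            raise ValueError("predict_proba requires the qualitative task")
        return self.predict(X, cells)

    def input_saliency(self, seq, cell: int, feature: int, guided: bool = True):
        self._require_fitted()
        return self.net_.input_saliency(np.asarray(seq, float), cell, feature, guided)

    def save(self, path) -> None:
        self._require_fitted()
        self.net_.save(path)

    @classmethod
    def from_network(cls, net: Network) -> "EpigenomeNet":
        cfg = net.config
        est = cls(
            task=cfg.task,
            head_variant=cfg.head_variant,
            emb_length=cfg.emb_length,
            seq_embedding_size=cfg.seq_embedding_size,
            conv_spec=cfg.conv_spec,
            head_depth=cfg.head_depth,
            head_width=cfg.head_width,
            input_length=cfg.input_length,
            seed=cfg.seed,
        )
        est.net_ = net
        est.n_cells_ = cfg.n_cells
        est.n_features_ = cfg.n_features
        est.embedding_ = net.get_cell_embeddings()
        est.history_ = []
        return est

    @classmethod
    def load(cls, path) -> "EpigenomeNet":
        return cls.from_network(Network.load(path))
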