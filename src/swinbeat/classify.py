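"""Scikit-learn estimator around the windowed-attention network.

:class:`SwinClassifier` trains :class:`~swinbeat.swin.SwinNet` with mean
softmax cross-entropy and Adam on mini-batches, and exposes the usual
``fit`` / ``predict`` / ``predict_proba`` surface, so it composes with
sklearn pipelines and model selection. Inputs are square RGB images
(``n, img_size, img_size, 3``) with values in [0, 1] — typically rendered
wavelet time-frequency maps.

Default architecture settings are the CPU-sized tiny-test configuration;
pass ``embed_dim=96, depths=(2, 2, 6, 2), num_heads=(3, 6, 12, 24),
window_size=7, img_size=224, lr=1e-4`` for the full-scale recipe.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, cross_entropy, softmax
from .swin import ModelConfig, SwinNet

__all__ = ["SwinClassifier"]


class SwinClassifier(ClassifierMixin, BaseEstimator):
    """Hierarchical window-attention image classifier.

    Parameters
    ----------
    img_size, patch_size, embed_dim, depths, num_heads, window_size,
    mlp_ratio, drop_rate, rel_pos_bias :
        Architecture hyperparameters, see :class:`~swinbeat.swin.ModelConfig`.
    lr, betas, batch_size, epochs :
        Adam optimizer and schedule settings.
    class_weight : {None, "balanced"}
        Optional inverse-frequency loss weighting.
    seed : int
        Controls initialization, batch shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of unique labels seen in ``fit``.
    loss_curve_ : list of per-epoch mean training losses.
    model_ : the fitted :class:`SwinNet`.
    """

    def __init__(self, img_size: int = 32, patch_size: int = 4,
                 embed_dim: int = 16, depths: tuple[int, ...] = (2, 2, 2, 2),
                 num_heads: tuple[int, ...] = (2, 2, 2, 2),
                 window_size: int = 4, mlp_ratio: float = 2.0,
                 drop_rate: float = 0.0, rel_pos_bias: bool = True,
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 batch_size: int = 32, epochs: int = 30,
                 class_weight: str | None = None, seed: int = 0,
                 verbose: int = 0):
        self.img_size = img_size
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.depths = depths
        self.num_heads = num_heads
        self.window_size = window_size
        self.mlp_ratio = mlp_ratio
        self.drop_rate = drop_rate
        self.rel_pos_bias = rel_pos_bias
        self.lr = lr
        self.betas = betas
        self.batch_size = batch_size
        self.epochs = epochs
        self.class_weight = class_weight
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _model_config(self, num_classes: int) -> ModelConfig:
        return ModelConfig(
            img_size=self.img_size, patch_size=self.patch_size,
            embed_dim=self.embed_dim, depths=tuple(self.depths),
            num_heads=tuple(self.num_heads), window=self.window_size,
            num_classes=num_classes, mlp_ratio=self.mlp_ratio,
            drop_rate=self.drop_rate, rel_pos_bias=self.rel_pos_bias,
            seed=self.seed)

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != (self.img_size, self.img_size, 3):
            raise ValueError(
                f"X must have shape (n, {self.img_size}, {self.img_size}, 3),"
                f" got {X.shape}")
        return X

    def fit(self, X, y):
        """Train on images ``X`` and labels ``y`` until ``epochs`` elapse."""
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        net = SwinNet(self._model_config(len(self.classes_)))
        opt = Adam(net.parameters(), lr=self.lr, betas=tuple(self.betas))
        rng = np.random.default_rng(self.seed)
        weights = None
        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=len(self.classes_))
            weights = len(y_idx) / (len(self.classes_) * np.maximum(counts, 1))
        n = len(X)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = net.forward(X[idx], train=True)
                loss, dlogits = cross_entropy(logits, y_idx[idx], weights)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss {loss} at epoch {epoch}; "
                        "lower the learning rate")
                net.zero_grad()
                net.backward(dlogits)
                opt.step()
                losses.append(loss * len(idx))
            self.loss_curve_.append(float(np.sum(losses) / n))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} "
                      f"loss {self.loss_curve_[-1]:.4f}")
        self.model_ = net
        self.n_features_in_ = X[0].size
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw class logits."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        out = np.empty((len(X), len(self.classes_)), dtype=np.float64)
        for start in range(0, len(X), max(1, self.batch_size)):
            out[start:start + self.batch_size] = self.model_.forward(
                X[start:start + self.batch_size])
        return out

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
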