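"""One-block 1-D DenseNet classifier for spectral / fused feature vectors.

The input is a 1-D feature vector treated as a single-channel sequence.
A stem convolution produces the initial feature maps; a single dense
block follows, in which every layer receives the concatenation of the
stem output and all preceding layers' outputs and contributes
``growth_rate`` new channels (so layer l sees
``init_channels + (l-1) * growth_rate`` input channels).  The block's
full concatenation is globally average-pooled and mapped to class
logits by one dense layer.  Trained with Adam on softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = ["DenseNet1DClassifier"]


class DenseNet1DClassifier(ClassifierMixin, BaseEstimator):
    """Single-dense-block 1-D convolutional classifier.

    Parameters
    ----------
    layers_in_block : convolutional layers inside the dense block (4).
    growth_rate : channels added per dense layer (12).
    kernel : convolution kernel size (3, zero-padded, stride 1).
    init_channels : channels produced by the stem convolution (16).
    epochs, batch_size, lr, seed : Adam training schedule and RNG seed.
    """

    def __init__(self, layers_in_block: int = 4, growth_rate: int = 12,
                 kernel: int = 3, init_channels: int = 16, epochs: int = 100,
                 batch_size: int = 16, lr: float = 1e-3, seed: int = 0):
        self.layers_in_block = layers_in_block
        self.growth_rate = growth_rate
        self.kernel = kernel
        self.init_channels = init_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _build(self, n_classes: int, rng: np.random.Generator) -> None:
        pad = self.kernel // 2
        self.stem_ = nn.Conv1d(1, self.init_channels, self.kernel, rng, pad=pad)
        self.block_ = []
        for l in range(self.layers_in_block):
            c_in = self.init_channels + l * self.growth_rate
            self.block_.append(nn.Conv1d(c_in, self.growth_rate, self.kernel, rng, pad=pad))
        total = self.init_channels + self.layers_in_block * self.growth_rate
        self.head_ = nn.Dense(total, n_classes, rng)
        self._relus_stem = nn.ReLU()
        self._relus_block = [nn.ReLU() for _ in self.block_]
        self._gap = nn.GlobalAvgPool1d()
        self._all_layers = [self.stem_, *self.block_, self.head_]

    def _forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n, length) -> logits (n, n_classes); caches for backward."""
        h = self._relus_stem.forward(self.stem_.forward(x[:, None, :]))
        feats = [h]
        self._concat_sizes = []
        for conv, relu in zip(self.block_, self._relus_block):
            cat = np.concatenate(feats, axis=1)
            self._concat_sizes.append([f.shape[1] for f in feats])
            feats.append(relu.forward(conv.forward(cat)))
        self._final_sizes = [f.shape[1] for f in feats]
        final = np.concatenate(feats, axis=1)
        return self.head_.forward(self._gap.forward(final))

    def _backward(self, grad_logits: np.ndarray) -> None:
        g = self._gap.backward(self.head_.backward(grad_logits))
        # split the final concatenation back into per-layer gradients
        splits = np.cumsum(self._final_sizes)[:-1]
        gfeats = list(np.split(g, splits, axis=1))
        for li in range(len(self.block_) - 1, -1, -1):
            gout = self._relus_block[li].backward(gfeats.pop())
            gcat = self.block_[li].backward(gout)
            sub = np.split(gcat, np.cumsum(self._concat_sizes[li])[:-1], axis=1)
            for k in range(len(gfeats)):
                gfeats[k] = gfeats[k] + sub[k]
        self.stem_.backward(self._relus_stem.backward(gfeats[0]))

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to train")
        y_idx = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed)
        self._build(self.classes_.size, rng)
        opt = nn.Adam(self._all_layers, lr=self.lr)
        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(X[idx])
                loss, grad = nn.softmax_cross_entropy(logits, y_idx[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                self._backward(grad)
                opt.step()
                epoch_loss += loss * idx.size
            self.loss_curve_.append(epoch_loss / n)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self._forward(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
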