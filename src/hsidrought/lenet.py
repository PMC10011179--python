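"""LeNet-5 image-feature extraction.

The classic LeNet-5 layout — two 5x5 convolutions (6 then 16 maps),
two 2x2 average pools, two fully connected layers (120, 84) and a
3-class output — is trained as a drought-stress classifier on RIS
stacks, then frozen and used as a feature extractor: image features are
the tapped layer's *pre-activation* outputs (by default the second
fully connected layer, giving an 84-dimensional vector; the 3-d output
layer pre-activation is available via ``feature_tap``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = ["LeNet5Features"]


class LeNet5Features(TransformerMixin, BaseEstimator):
    """Train LeNet-5 as a classifier; ``transform`` yields image features.

    Parameters
    ----------
    input_hw : side length of the (square) input stack, default 32.
    in_channels : number of RIS images stacked as input channels.
    n_classes : number of stress classes (3).
    feature_tap : ``"fc2_preactivation"`` (84-d, default) or
        ``"output_preactivation"`` (n_classes-d) — the layer whose
        pre-activation values serve as image features.
    epochs, batch_size, lr : Adam training schedule.
    seed : controls init and minibatch shuffling; same seed, same weights.
    """

    def __init__(self, input_hw: int = 32, in_channels: int = 1, n_classes: int = 3,
                 feature_tap: str = "fc2_preactivation", epochs: int = 30,
                 batch_size: int = 16, lr: float = 1e-3, seed: int = 0):
        self.input_hw = input_hw
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.feature_tap = feature_tap
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # architecture: conv5(6) -> pool2 -> conv5(16) -> pool2 -> fc120 -> fc84 -> fc{n_classes}
    def _build(self, rng: np.random.Generator) -> None:
        hw = self.input_hw
        h2 = (hw - 4) // 2          # after conv1 + pool1
        h3 = (h2 - 4) // 2          # after conv2 + pool2
        if h3 < 1:
            raise ValueError(f"input_hw={hw} too small for the LeNet-5 stack")
        self._flat_dim = 16 * h3 * h3
        self.conv1_ = nn.Conv2d(self.in_channels, 6, 5, rng)
        self.conv2_ = nn.Conv2d(6, 16, 5, rng)
        self.fc1_ = nn.Dense(self._flat_dim, 120, rng)
        self.fc2_ = nn.Dense(120, 84, rng)
        self.out_ = nn.Dense(84, self.n_classes, rng)
        self.layers_ = [
            self.conv1_, nn.ReLU(), nn.AvgPool2d(2),
            self.conv2_, nn.ReLU(), nn.AvgPool2d(2),
            nn.Flatten(), self.fc1_, nn.ReLU(),
            self.fc2_, nn.ReLU(), self.out_,
        ]

    def _forward(self, x: np.ndarray, tap: str | None = None) -> np.ndarray:
        taps = {"fc2_preactivation": self.fc2_, "output_preactivation": self.out_}
        tap_layer = taps.get(tap) if tap else None
        out = x
        for layer in self.layers_:
            out = layer.forward(out)
            if layer is tap_layer:
                return out
        return out

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(f"expected stacks (n, channels, h, w), got shape {X.shape}")
        if X.shape[1:] != (self.in_channels, self.input_hw, self.input_hw):
            raise ValueError(
                f"stack shape {X.shape[1:]} != configured "
                f"({self.in_channels}, {self.input_hw}, {self.input_hw})"
            )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to train")
        if self.feature_tap not in ("fc2_preactivation", "output_preactivation"):
            raise ValueError(f"unknown feature_tap {self.feature_tap!r}")
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        opt = nn.Adam(self.layers_, lr=self.lr)
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
                for layer in reversed(self.layers_):
                    grad = layer.backward(grad)
                opt.step()
                epoch_loss += loss * idx.size
            self.loss_curve_.append(epoch_loss / n)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Image features: pre-activation outputs of the tapped layer."""
        check_is_fitted(self, "layers_")
        return self._forward(self._check_X(X), tap=self.feature_tap)

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "layers_")
        logits = self._forward(self._check_X(X))
        return self.classes_[np.argmax(logits, axis=1)]

    def save(self, path: str) -> None:
        """Write weights as a single ``.npz`` plus a ``.json`` config sidecar."""
        import json

        check_is_fitted(self, "layers_")
        arrays = {}
        for li, layer in enumerate(self.layers_):
            for pi, p in enumerate(layer.params):
                arrays[f"l{li}_p{pi}"] = p
        np.savez(path, classes=self.classes_, **arrays)
        with open(path + ".json", "w") as fh:
            json.dump(self.get_params(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "LeNet5Features":
        import json

        with open(path + ".json") as fh:
            est = cls(**json.load(fh))
        data = np.load(path if path.endswith(".npz") else path + ".npz")
        est.classes_ = data["classes"]
        est._build(np.random.default_rng(est.seed))
        est.loss_curve_ = []
        for li, layer in enumerate(est.layers_):
            for pi in range(len(layer.params)):
                layer.params[pi][...] = data[f"l{li}_p{pi}"]
        return est

    def weights_checksum(self) -> float:
        """Deterministic scalar fingerprint of all trained weights."""
        check_is_fitted(self, "layers_")
        return float(sum(np.abs(p).sum() for l in self.layers_ for p in l.params))
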