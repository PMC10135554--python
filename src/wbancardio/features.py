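"""Deep feature extraction from vital-sign records.

Two extractors, both treating a record's three standardized vitals as a length-3
one-channel sequence:

* :class:`ConvAutoencoder` — an unsupervised convolutional autoencoder; the
  bottleneck activations are the feature set.
* :class:`Conv1DFeatures` — a small supervised 1-D CNN trained on the binary
  label; the penultimate (pre-classification) activations are the feature set.

Their column-wise concatenation is the integrated deep-feature matrix passed
to the wrapper feature-selection stage. Both are sklearn-style transformers
(``fit`` / ``transform``) and are deterministic given ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.utils.validation import check_is_fitted

from ._nn import (
    Adam,
    Conv1D,
    Dense,
    Flatten,
    ReLU,
    Sequential,
    balanced_weights,
    bce_with_logits,
    check_finite,
    mse_loss,
)


@dataclass
class FeatureSet:
    """An ``n x d`` feature matrix tagged with its source extractor."""

    matrix: np.ndarray
    source: str  # autoencoder | cnn1d | concatenated

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite entries")


def concatenate(ae: FeatureSet, cnn: FeatureSet) -> FeatureSet:
    """Column-wise concatenation; both operands preserved bit-exactly."""
    if ae.matrix.shape[0] != cnn.matrix.shape[0]:
        raise ValueError(
            f"row mismatch: {ae.matrix.shape[0]} vs {cnn.matrix.shape[0]}"
        )
    return FeatureSet(np.hstack([ae.matrix, cnn.matrix]), "concatenated")


class _StandardizedNet(BaseEstimator):
    """Shared plumbing: per-column z-scoring with training-fold statistics."""

    def _standardize_fit(self, X):
        # C-contiguity keeps BLAS summation order, hence training, independent
        # of the caller's array memory layout
        X = np.ascontiguousarray(X, float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        self.n_features_in_ = X.shape[1]
        return np.ascontiguousarray((X - self.mean_) / self.scale_)

    def _standardize(self, X):
        X = np.ascontiguousarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got shape {X.shape}"
            )
        return np.ascontiguousarray((X - self.mean_) / self.scale_)

    def _iterate(self, n, rng):
        for _, batch in self._iterate_epochs(n, rng):
            yield batch

    def _iterate_epochs(self, n, rng):
        idx = np.arange(n)
        for epoch in range(self.epochs):
            rng.shuffle(idx)
            for start in range(0, n, self.batch_size):
                yield epoch, idx[start : start + self.batch_size]


class ConvAutoencoder(_StandardizedNet, TransformerMixin):
    """Convolutional autoencoder over the standardized vitals sequence.

    Encoder: Conv1D(1 -> n_filters, kernel_size) -> activation -> flatten ->
    dense bottleneck of ``bottleneck_dim`` units. Decoder mirrors with dense
    layers back to the input width. Trained by Adam on mean squared
    reconstruction error. ``activation='linear'`` removes the nonlinearities
    (PCA-like capacity).
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel_size: int = 2,
        bottleneck_dim: int = 8,
        activation: str = "relu",
        epochs: int = 300,
        lr: float = 0.01,
        batch_size: int = 128,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.bottleneck_dim = bottleneck_dim
        self.activation = activation
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state

    def _build(self, d_in, rng):
        width = (d_in - self.kernel_size + 1) * self.n_filters
        act = (lambda: [ReLU()]) if self.activation == "relu" else (lambda: [])
        enc = [Conv1D(1, self.n_filters, self.kernel_size, rng), *act(), Flatten(),
               Dense(width, self.bottleneck_dim, rng)]
        dec = [Dense(self.bottleneck_dim, width, rng), *act(), Dense(width, d_in, rng)]
        return Sequential(enc), Sequential(dec)

    def fit(self, X, y=None):
        Xs = self._standardize_fit(X)
        if Xs.shape[0] < 1:
            raise ValueError("need at least one training record")
        rng = np.random.default_rng(self.random_state)
        self.encoder_, self.decoder_ = self._build(Xs.shape[1], rng)
        opt = Adam(self.encoder_.params + self.decoder_.params, lr=self.lr)
        self.loss_curve_ = []
        for batch in self._iterate(Xs.shape[0], rng):
            xb = Xs[batch][:, :, None]
            z = self.encoder_.forward(xb)
            recon = self.decoder_.forward(z)
            loss, grad = mse_loss(recon, Xs[batch])
            check_finite(loss)
            self.loss_curve_.append(loss)
            dz = self.decoder_.backward(grad)
            self.encoder_.backward(dz)
            opt.step(self.encoder_.grads + self.decoder_.grads)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        Xs = self._standardize(X)
        return self.encoder_.forward(Xs[:, :, None])

    def reconstruct(self, X) -> np.ndarray:
        """Decoder output in standardized units (for reconstruction-error checks)."""
        return self.decoder_.forward(self.transform(X))

    def reconstruction_mse(self, X) -> float:
        Xs = self._standardize(X)
        return float(np.mean((self.reconstruct(X) - Xs) ** 2))


class Conv1DFeatures(_StandardizedNet, TransformerMixin):
    """Supervised 1-D CNN; ``transform`` returns penultimate-layer activations.

    Architecture: Conv1D(1 -> n_filters, kernel_size) -> ReLU -> flatten ->
    dense ``d_out`` -> ReLU (the feature layer) -> dense 1-logit head, trained
    with binary cross-entropy on the disease label.
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel_size: int = 2,
        d_out: int = 8,
        epochs: int = 300,
        lr: float = 0.01,
        batch_size: int = 128,
        class_weight: str | None = "balanced",
        weight_decay: float = 5e-4,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.d_out = d_out
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.weight_decay = weight_decay
        self.random_state = random_state

    def fit(self, X, y):
        Xs = self._standardize_fit(X)
        y = np.asarray(y, float).reshape(-1)
        if y.shape[0] != Xs.shape[0]:
            raise ValueError("X and y length mismatch")
        weights = balanced_weights(y) if self.class_weight == "balanced" else None
        rng = np.random.default_rng(self.random_state)
        width = (Xs.shape[1] - self.kernel_size + 1) * self.n_filters
        self.net_ = Sequential(
            [
                Conv1D(1, self.n_filters, self.kernel_size, rng),
                ReLU(),
                Flatten(),
                Dense(width, self.d_out, rng),
                ReLU(),  # penultimate feature layer
                Dense(self.d_out, 1, rng),
            ]
        )
        opt = Adam(self.net_.params, lr=self.lr)
        self.loss_curve_ = []
        for epoch, batch in self._iterate_epochs(Xs.shape[0], rng):
            if epoch == (3 * self.epochs) // 4:
                opt.lr = self.lr / 5.0  # settle the boundary late in training
            logits = self.net_.forward(Xs[batch][:, :, None])
            loss, grad = bce_with_logits(
                logits, y[batch], None if weights is None else weights[batch]
            )
            check_finite(loss)
            self.loss_curve_.append(loss)
            self.net_.backward(grad)
            opt.step(self.net_.grads, self.weight_decay)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        Xs = self._standardize(X)
        # forward through all layers except the classification head
        return self.net_.forward(Xs[:, :, None], upto=-1)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.forward(self._standardize(X)[:, :, None]).reshape(-1)

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


class DeepFeatureUnion(BaseEstimator, TransformerMixin):
    """Fits both extractors on the training fold and concatenates their outputs."""

    def __init__(self, ae: ConvAutoencoder | None = None, cnn: Conv1DFeatures | None = None):
        self.ae = ae
        self.cnn = cnn

    def fit(self, X, y=None):
        self.ae_ = clone(self.ae) if self.ae is not None else ConvAutoencoder()
        self.cnn_ = clone(self.cnn) if self.cnn is not None else Conv1DFeatures()
        self.ae_.fit(X)
        self.cnn_.fit(X, y)
        self.d_ae_ = self.ae_.bottleneck_dim
        self.d_cnn_ = self.cnn_.d_out
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "ae_")
        return np.hstack([self.ae_.transform(X), self.cnn_.transform(X)])


# --- thin functional surface -------------------------------------------------

def train_autoencoder(X, **params) -> ConvAutoencoder:
    return ConvAutoencoder(**params).fit(X)


def extract_ae_features(encoder: ConvAutoencoder, X) -> FeatureSet:
    return FeatureSet(encoder.transform(X), "autoencoder")


def train_cnn1d(X, y, **params) -> Conv1DFeatures:
    return Conv1DFeatures(**params).fit(X, y)


def extract_cnn_features(network: Conv1DFeatures, X) -> FeatureSet:
    return FeatureSet(network.transform(X), "cnn1d")
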