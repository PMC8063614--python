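"""High-order feature extraction and cross-feature interaction.

Each similarity view (FS, SS, GS_m, GS_d) is compressed by a stacked
autoencoder trained greedily layer by layer: layer 1 reconstructs the
similarity rows, layer 2 reconstructs layer 1's codes, and so on.  The
final code (64-d by default) is the "high-order feature" of the entity.
Per sample pair, one miRNA-side code and one disease-side code are
concatenated into a cross feature; the four miRNA x disease view
pairings give blocks D1-D4.

The autoencoder minimises, per layer,

    H = (1/2) sum_k ||x_k - y_k||^2 + lambda * ||theta||^2

with sigmoid activations on both encoder and decoder (inputs are
similarities in [0, 1]), untied weights, and full-batch gradient
descent.  The update step uses the per-sample mean of the objective so
the learning rate is independent of the batch size; the recorded
``loss_history_`` reports the summed form above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["StackedAutoencoder", "CrossFeatureSet", "build_cross_features", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class StackedAutoencoder(BaseEstimator, TransformerMixin):
    """Greedy layer-wise stacked autoencoder with sigmoid units.

    Parameters
    ----------
    layer_sizes : tuple of int, default (256, 128, 64)
        Hidden widths; must be strictly decreasing.  The last entry is
        the high-order feature dimension.
    weight_decay : float, default 1e-4
        L2 penalty ``lambda`` on all weights and biases.
    epochs_per_layer : int, default 500
        Full-batch gradient steps per layer.
    learning_rate : float, default 0.1
        Step size on the per-sample-mean objective.
    random_state : int, default 0
        Seeds the Glorot-uniform weight initialisation.

    Attributes
    ----------
    encoders_ : list of (W1, b1)
        Per-layer encoding weights, ``W1`` of shape (width, fan_in).
    decoders_ : list of (W2, b2)
        Per-layer decoding weights, ``W2`` of shape (fan_in, width).
    loss_history_ : list of ndarray
        Per-layer objective trajectory; entry 0 of each array is the
        loss at initialisation, before any update.
    """

    def __init__(
        self,
        layer_sizes=(256, 128, 64),
        weight_decay: float = 1e-4,
        epochs_per_layer: int = 500,
        learning_rate: float = 0.1,
        random_state: int = 0,
    ):
        self.layer_sizes = layer_sizes
        self.weight_decay = weight_decay
        self.epochs_per_layer = epochs_per_layer
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _validate(self, X):
        X = check_array(X, dtype=float)
        if X.min() < 0 or X.max() > 1:
            raise ValueError("autoencoder inputs must lie in [0, 1] (sigmoid output range)")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        sizes = tuple(int(s) for s in self.layer_sizes)
        if not sizes:
            raise ValueError("layer_sizes must be non-empty")
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"layer_sizes must be strictly decreasing, got {sizes}")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        rng = np.random.default_rng(self.random_state)
        self.encoders_, self.decoders_, self.loss_history_ = [], [], []
        H = X
        for width in sizes:
            W1, b1, W2, b2, losses = self._train_layer(H, width, rng)
            self.encoders_.append((W1, b1))
            self.decoders_.append((W2, b2))
            self.loss_history_.append(np.asarray(losses))
            H = sigmoid(H @ W1.T + b1)
        self.n_features_in_ = X.shape[1]
        return self

    def _train_layer(self, X, width, rng):
        m, n = X.shape
        lam, lr = self.weight_decay, self.learning_rate

        def glorot(fan_out, fan_in):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_out, fan_in))

        W1, b1 = glorot(width, n), np.zeros(width)
        W2, b2 = glorot(n, width), np.zeros(n)

        def objective(Y, theta):
            recon = 0.5 * np.sum((X - Y) ** 2)
            return recon + lam * sum(np.sum(t**2) for t in theta)

        losses = []
        for _ in range(self.epochs_per_layer):
            G = sigmoid(X @ W1.T + b1)
            Y = sigmoid(G @ W2.T + b2)
            losses.append(objective(Y, (W1, b1, W2, b2)))
            # backprop on the per-sample mean of the objective
            dY = (Y - X) * Y * (1.0 - Y) / m
            gW2 = dY.T @ G + 2.0 * lam * W2 / m
            gb2 = dY.sum(axis=0) + 2.0 * lam * b2 / m
            dG = (dY @ W2) * G * (1.0 - G)
            gW1 = dG.T @ X + 2.0 * lam * W1 / m
            gb1 = dG.sum(axis=0) + 2.0 * lam * b1 / m
            W1 -= lr * gW1
            b1 -= lr * gb1
            W2 -= lr * gW2
            b2 -= lr * gb2
        G = sigmoid(X @ W1.T + b1)
        Y = sigmoid(G @ W2.T + b2)
        losses.append(objective(Y, (W1, b1, W2, b2)))
        return W1, b1, W2, b2, losses

    def transform(self, X) -> np.ndarray:
        """Apply the composed encoders; output width is the last layer size."""
        check_is_fitted(self, "encoders_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} does not match the fitted width {self.n_features_in_}"
            )
        H = X
        for W1, b1 in self.encoders_:
            H = sigmoid(H @ W1.T + b1)
        return H

    def reconstruct(self, X) -> np.ndarray:
        """Encode through all layers then decode back (diagnostic use)."""
        check_is_fitted(self, "encoders_")
        H = self.transform(X)
        for W2, b2 in reversed(self.decoders_):
            H = sigmoid(H @ W2.T + b2)
        return H


@dataclass
class CrossFeatureSet:
    """The four interacted feature blocks, one row per sample pair.

    Each block concatenates one miRNA-side with one disease-side
    high-order feature:

    * D1 = [D_fs  | D_ss]
    * D2 = [D_gsm | D_ss]
    * D3 = [D_fs  | D_gsd]
    * D4 = [D_gsm | D_gsd]
    """

    D1: np.ndarray
    D2: np.ndarray
    D3: np.ndarray
    D4: np.ndarray

    def __post_init__(self):
        ns = {b.shape[0] for b in self.blocks}
        if len(ns) != 1:
            raise ValueError(f"cross blocks disagree on sample count: {sorted(ns)}")

    @property
    def blocks(self) -> tuple[np.ndarray, ...]:
        return (self.D1, self.D2, self.D3, self.D4)

    @property
    def n_samples(self) -> int:
        return self.D1.shape[0]

    def stacked(self) -> np.ndarray:
        """All four blocks side by side (for estimators taking one 2-d array)."""
        return np.hstack(self.blocks)

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(b.shape[1] for b in self.blocks)

    @classmethod
    def from_stacked(cls, X: np.ndarray, widths) -> "CrossFeatureSet":
        widths = tuple(widths)
        if X.shape[1] != sum(widths):
            raise ValueError(f"stacked width {X.shape[1]} != sum of block widths {widths}")
        edges = np.cumsum((0,) + widths)
        return cls(*[X[:, a:b] for a, b in zip(edges[:-1], edges[1:])])

    def subset(self, idx) -> "CrossFeatureSet":
        return CrossFeatureSet(*[b[idx] for b in self.blocks])


def build_cross_features(D_fs, D_ss, D_gsm, D_gsd) -> CrossFeatureSet:
    """Pair miRNA-side with disease-side high-order features.

    ``D_fs``/``D_gsm`` are per-sample miRNA codes, ``D_ss``/``D_gsd``
    per-sample disease codes; all must share the sample count, and the
    two views of one side must share their width.
    """
    arrs = [np.asarray(a, dtype=float) for a in (D_fs, D_ss, D_gsm, D_gsd)]
    ns = {a.shape[0] for a in arrs}
    if len(ns) != 1:
        raise ValueError(f"views disagree on sample count: {sorted(ns)}")
    D_fs, D_ss, D_gsm, D_gsd = arrs
    if D_fs.shape[1] != D_gsm.shape[1]:
        raise ValueError("miRNA-side views FS and GS_m disagree on width")
    if D_ss.shape[1] != D_gsd.shape[1]:
        raise ValueError("disease-side views SS and GS_d disagree on width")
    return CrossFeatureSet(
        D1=np.hstack([D_fs, D_ss]),
        D2=np.hstack([D_gsm, D_ss]),
        D3=np.hstack([D_fs, D_gsd]),
        D4=np.hstack([D_gsm, D_gsd]),
    )
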