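"""A small convolutional classifier for expression-pair instances.

Each instance is a (genes x 2) block: the same gene's standardized expression
in two samples. The first hidden layer applies 16 convolution filters with a
1x2 kernel across the sample axis — one learned contrast per gene between the
two samples, weights shared over genes. The filter maps feed two fully
connected layers of 32 and 16 units, all rectified-linear, and a 2-way
softmax output (primary-primary vs primary-recurrent). Cross-entropy loss is
minimized with Adagrad.

The network is implemented directly in numpy: models are tiny (tens of genes,
hundreds of pairs), so explicit forward/backward passes are fast, dependency
free, and bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Architecture and training constants of the pairwise classifier."""

    n_genes: int
    conv_filters: int = 16
    dense_units: tuple[int, int] = (32, 16)
    epochs: int = 100
    learning_rate: float = 0.05
    batch_size: int = 32
    pp_pr_ratio: float = 1.0  # PP pairs kept per PR pair in each training epoch

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


class PairConvNet:
    """16-filter 1x2 conv -> dense(32) -> dense(16) -> softmax(2), numpy."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        g, f = spec.n_genes, spec.conv_filters
        d1, d2 = spec.dense_units
        def glorot(fan_in, fan_out, shape):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)
        self.W1 = glorot(2, f, (f, 2))          # conv kernel over the 2-sample axis
        self.b1 = np.zeros(f)
        self.W2 = glorot(g * f, d1, (g * f, d1))
        self.b2 = np.zeros(d1)
        self.W3 = glorot(d1, d2, (d1, d2))
        self.b3 = np.zeros(d2)
        self.W4 = glorot(d2, 2, (d2, 2))
        self.b4 = np.zeros(2)
        self._params = ["W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4"]
        self._accum = {p: np.zeros_like(getattr(self, p)) for p in self._params}

    # forward -------------------------------------------------------------
    def _forward(self, X: np.ndarray):
        # X: (n, genes, 2)
        H1 = np.maximum(X @ self.W1.T + self.b1, 0.0)        # (n, g, f)
        F = H1.reshape(X.shape[0], -1)                        # (n, g*f)
        H2 = np.maximum(F @ self.W2 + self.b2, 0.0)
        H3 = np.maximum(H2 @ self.W3 + self.b3, 0.0)
        logits = H3 @ self.W4 + self.b4
        z = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(z)
        proba = expz / expz.sum(axis=1, keepdims=True)
        return H1, F, H2, H3, proba

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, column 1 = primary-recurrent."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return self._forward(X)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # training ------------------------------------------------------------
    def _step(self, X: np.ndarray, y: np.ndarray, lr: float, eps: float = 1e-8) -> float:
        n = X.shape[0]
        H1, F, H2, H3, proba = self._forward(X)
        logp = np.log(np.clip(proba[np.arange(n), y], 1e-12, None))
        loss = -logp.mean()
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss on batch of {n} (labels {np.bincount(y)})")

        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {}
        grads["W4"] = H3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dH3 = (dlogits @ self.W4.T) * (H3 > 0)
        grads["W3"] = H2.T @ dH3
        grads["b3"] = dH3.sum(axis=0)
        dH2 = (dH3 @ self.W3.T) * (H2 > 0)
        grads["W2"] = F.T @ dH2
        grads["b2"] = dH2.sum(axis=0)
        dF = dH2 @ self.W2.T
        dH1 = dF.reshape(H1.shape) * (H1 > 0)
        grads["W1"] = np.einsum("ngf,ngc->fc", dH1, X)
        grads["b1"] = dH1.sum(axis=(0, 1))

        for p in self._params:
            gr = grads[p]
            self._accum[p] += gr * gr
            getattr(self, p)[...] -= lr * gr / (np.sqrt(self._accum[p]) + eps)
        return float(loss)

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> list[float]:
        """Train with per-epoch rebalancing of the majority PP class.

        Each epoch subsamples PP instances to ``pp_pr_ratio`` times the PR
        count (all PR instances kept), shuffles, and runs minibatch Adagrad.
        Returns the per-epoch mean losses.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        pp_idx = np.flatnonzero(y == 0)
        pr_idx = np.flatnonzero(y == 1)
        if len(pp_idx) == 0 or len(pr_idx) == 0:
            raise TrainingError("both classes must be present in the training set")
        spec = self.spec
        losses = []
        for _ in range(spec.epochs):
            n_pp = min(len(pp_idx), max(1, int(round(spec.pp_pr_ratio * len(pr_idx)))))
            chosen_pp = rng.choice(pp_idx, size=n_pp, replace=False)
            idx = np.concatenate([chosen_pp, pr_idx])
            rng.shuffle(idx)
            epoch_losses = []
            for start in range(0, len(idx), spec.batch_size):
                batch = idx[start : start + spec.batch_size]
                epoch_losses.append(self._step(X[batch], y[batch], spec.learning_rate))
            losses.append(float(np.mean(epoch_losses)))
        return losses
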