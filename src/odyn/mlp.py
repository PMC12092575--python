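"""A small fully-connected classifier trained with symmetric cross-entropy.

The risk-scoring head is a 168-64-2 multilayer perceptron with a leaky
ReLU activation and dropout (0.2) after the hidden layer, optimized with
Adam. The network is small enough that an explicit numpy implementation is
the simplest way to guarantee bit-reproducible training on one CPU; the
forward/backward passes and the optimizer live here.

Symmetric cross-entropy (SCE) combines the usual cross-entropy CE(q, p)
with a reverse term RCE(p, q) in which prediction and one-hot label swap
roles; log 0 arising from the one-hot label is replaced by a finite clamp
A (default -4), so for a two-class problem

    SCE = alpha * (-log p_y) + beta * (-(1 - p_y) * A).

With beta = 0 the loss reduces exactly to cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of the scoring network (input-hidden-output widths)."""

    n_in: int = 168
    n_hidden: int = 64
    n_out: int = 2
    leaky_slope: float = 0.01
    dropout: float = 0.2
    param_seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """IDaRS training hyper-parameters.

    k top-ranked plus r random patches are drawn per slide per epoch
    (k=5, r=45 by default) and optimized in minibatches of 256 with Adam.
    """

    k: int = 5
    r: int = 45
    batch_size: int = 256
    learning_rate: float = 1e-3
    epochs: int = 50
    sce_alpha: float = 1.0
    sce_beta: float = 1.0
    log_clamp: float = -4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0 or self.r < 0 or self.k + self.r < 1:
            raise ValueError("need k >= 0, r >= 0, k + r >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sce_loss(
    probabilities: np.ndarray,
    label: int,
    alpha: float = 1.0,
    beta: float = 1.0,
    log_clamp: float = -4.0,
    tol: float = 1e-6,
) -> float:
    """Symmetric cross-entropy of one predicted class distribution.

    ``probabilities`` must lie on the simplex (checked to ``tol``). Returns
    alpha * CE + beta * RCE with the reverse term's log 0 clamped.
    """
    p = np.asarray(probabilities, dtype=float)
    if abs(p.sum() - 1.0) > tol or np.any(p < -tol):
        raise ValueError(f"probabilities off the simplex: {p}")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    p_y = float(np.clip(p[label], 1e-300, 1.0))
    ce = -np.log(p_y)
    rce = -(1.0 - p[label]) * log_clamp
    return float(alpha * ce + beta * rce)


class MLP:
    """168-64-2 network with leaky ReLU, dropout, Adam, and SCE loss."""

    def __init__(self, spec: MLPSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.param_seed)
        s1 = np.sqrt(2.0 / spec.n_in)
        s2 = np.sqrt(2.0 / spec.n_hidden)
        self.W1 = rng.normal(0.0, s1, (spec.n_in, spec.n_hidden))
        self.b1 = np.zeros(spec.n_hidden)
        self.W2 = rng.normal(0.0, s2, (spec.n_hidden, spec.n_out))
        self.b2 = np.zeros(spec.n_out)
        self._adam_state: dict | None = None

    # -- inference ---------------------------------------------------------

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        h = X @ self.W1 + self.b1
        return np.where(h > 0, h, self.spec.leaky_slope * h)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities with dropout disabled (inference mode)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.n_in:
            raise ValueError(f"expected (n, {self.spec.n_in}) features, got {X.shape}")
        return softmax(self._hidden(X) @ self.W2 + self.b2)

    # -- training ----------------------------------------------------------

    def train_step(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                   rng: np.random.Generator) -> float:
        """One Adam minibatch update on the SCE loss; returns the mean loss."""
        n = len(X)
        pre = X @ self.W1 + self.b1
        act = np.where(pre > 0, pre, self.spec.leaky_slope * pre)
        if self.spec.dropout > 0:
            keep = rng.random(act.shape) >= self.spec.dropout
            act = act * keep / (1.0 - self.spec.dropout)
        logits = act @ self.W2 + self.b2
        p = softmax(logits)
        p_y = p[np.arange(n), y]

        loss = float(np.mean(
            -cfg.sce_alpha * np.log(np.clip(p_y, 1e-300, None))
            - cfg.sce_beta * (1.0 - p_y) * cfg.log_clamp
        ))

        # d(loss)/d(logits): CE term p - onehot; RCE term A*p_y*(onehot - p)
        onehot = np.zeros_like(p)
        onehot[np.arange(n), y] = 1.0
        dlogits = cfg.sce_alpha * (p - onehot)
        dlogits += cfg.sce_beta * cfg.log_clamp * p_y[:, None] * (onehot - p)
        dlogits /= n

        dW2 = act.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dact = dlogits @ self.W2.T
        if self.spec.dropout > 0:
            dact = dact * keep / (1.0 - self.spec.dropout)
        dpre = dact * np.where(pre > 0, 1.0, self.spec.leaky_slope)
        dW1 = X.T @ dpre
        db1 = dpre.sum(axis=0)

        self._adam_update([dW1, db1, dW2, db2], cfg.learning_rate)
        return loss

    def _adam_update(self, grads: list[np.ndarray], lr: float,
                     beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        params = [self.W1, self.b1, self.W2, self.b2]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- (de)serialization -------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.copy(), "b1": self.b1.copy(),
                "W2": self.W2.copy(), "b2": self.b2.copy()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.W1 = params["W1"].copy()
        self.b1 = params["b1"].copy()
        self.W2 = params["W2"].copy()
        self.b2 = params["b2"].copy()
        self._adam_state = None

    def spec_dict(self) -> dict:
        return asdict(self.spec)
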