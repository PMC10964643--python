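"""Minimal fully-connected network machinery with manual backpropagation.

The generative augmentation models in :mod:`swpkit.augment` are small chains
of linear layers with rectifier activations, trained by plain stochastic
gradient descent. This module provides exactly that: an :class:`MLPNet` whose
forward pass caches what its backward pass needs, inverted dropout on hidden
activations, He-scaled initialization from an explicit ``numpy`` generator
(so training is bit-reproducible), and the numerically safe pieces of the
adversarial objective (log-sigmoid terms evaluated from logits).
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in))


class MLPNet:
    """Chain of linear layers, ReLU between them, linear output.

    Parameters
    ----------
    widths : sequence of int
        Layer sizes including input and output; ``len(widths) - 1`` weight
        maps. ``[411, 200, 100, 100, 50]`` is a 411-in, 50-out network with
        three hidden rectifier layers.
    rng : numpy.random.Generator
        Source of the initialization draws.
    dropout : float
        Inverted-dropout rate applied to hidden activations during training
        passes only.
    """

    def __init__(self, widths, rng: np.random.Generator, dropout: float = 0.0):
        if len(widths) < 2:
            raise ValueError("need at least an input and an output width")
        self.widths = tuple(int(w) for w in widths)
        self.dropout = float(dropout)
        self.W = [he_init(rng, a, b) for a, b in zip(self.widths[:-1], self.widths[1:])]
        self.b = [np.zeros(w) for w in self.widths[1:]]
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]
        self._cache = None

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Forward pass; caches intermediates for :meth:`backward`."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        inputs, masks = [], []
        h = x
        last = self.n_layers - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            inputs.append(h)
            z = h @ W.T + b
            if i < last:
                h = np.maximum(z, 0.0)
                if train and self.dropout > 0.0:
                    if rng is None:
                        raise ValueError("training pass with dropout needs an rng")
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                h = z
        self._cache = (inputs, masks)
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backprop ``d loss / d output``; stores parameter grads, returns d/d input."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        inputs, masks = self._cache
        grad = np.atleast_2d(np.asarray(grad_out, dtype=float))
        last = self.n_layers - 1
        for i in range(last, -1, -1):
            h_in = inputs[i]
            if i < last:
                # grad arrives w.r.t. post-dropout activation
                if masks[i] is not None:
                    grad = grad * masks[i]
                z = h_in @ self.W[i].T + self.b[i]
                grad = grad * (z > 0.0)
            self.gW[i] = grad.T @ h_in
            self.gb[i] = grad.sum(axis=0)
            grad = grad @ self.W[i]
        self._cache = None
        return grad

    def step(self, lr: float) -> None:
        """Plain SGD update with the most recent gradients."""
        for W, b, gW, gb in zip(self.W, self.b, self.gW, self.gb):
            W -= lr * gW
            b -= lr * gb

    def parameters(self) -> list[np.ndarray]:
        return list(self.W) + list(self.b)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically safe logistic; strictly inside (0, 1) for finite input."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log sigma(x), evaluated without overflow."""
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))


def bce_real_grad(logits: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and d/d logits of -mean log sigma(l)  (targets 'real')."""
    loss = float(-log_sigmoid(logits).mean())
    grad = (sigmoid(logits) - 1.0) / logits.size
    return loss, grad


def bce_fake_grad(logits: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and d/d logits of -mean log(1 - sigma(l))  (targets 'fake')."""
    loss = float(-(log_sigmoid(-logits)).mean())
    grad = sigmoid(logits) / logits.size
    return loss, grad


def l1_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-over-batch, sum-over-dimensions L1 loss and its gradient."""
    pred = np.atleast_2d(pred)
    target = np.atleast_2d(target)
    diff = pred - target
    loss = float(np.abs(diff).sum(axis=1).mean())
    grad = np.sign(diff) / pred.shape[0]
    return loss, grad
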