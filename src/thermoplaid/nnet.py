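"""A small trainable feed-forward network with exact input gradients.

Architecture used throughout the package: one *linear* convolutional layer of
20 units, each spanning the full (2 x 25-bin) history of both input channels
and acting as a learned temporal basis, followed by two 64-unit dense layers
with Swish activation, dropout after each layer, and a single linear output
unit approximating the log-odds of a swim bout.  Training minimizes binary
cross-entropy with an L2 weight-decay penalty using Adam.

Written directly on numpy so that the derivative of the scalar output with
respect to each input bin -- the quantity the receptive-field extraction
differentiates -- is available in closed form rather than by finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit


def _swish(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = expit(z)
    a = z * s
    return a, s * (1.0 + z * (1.0 - s))  # value, derivative


def _identity(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return z, np.ones_like(z)


_ACTIVATIONS: dict[str, Callable] = {"swish": _swish, "identity": _identity}


@dataclass
class NetSpec:
    """Architecture and training hyperparameters."""

    n_inputs: int = 50
    n_conv: int = 20
    n_dense: int = 64
    activation: str = "swish"
    dropout: float = 0.5
    weight_decay: float = 1e-5
    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


class MLP:
    """Conv(linear) -> dense -> dense -> linear logit network."""

    def __init__(self, spec: NetSpec, seed: int | None = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        sizes = [spec.n_inputs, spec.n_conv, spec.n_dense, spec.n_dense, 1]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(fan_out) for fan_out in sizes[1:]]
        self.loss_history: list[float] = []
        self.trained = False

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Return (logits, cache). ``rng`` enables inverted dropout (training)."""
        act = _ACTIVATIONS[self.spec.activation]
        p = self.spec.dropout
        caches = []
        h = x
        for layer in range(4):
            z = h @ self.weights[layer] + self.biases[layer]
            if layer == 0 or layer == 3:  # conv layer and output are linear
                a, da = z, None
            else:
                a, da = act(z)
            mask = None
            if rng is not None and p > 0 and layer < 3:  # dropout after conv + dense
                mask = (rng.uniform(size=a.shape) >= p) / (1.0 - p)
                a = a * mask
            caches.append((h, da, mask))
            h = a
        return h[:, 0], caches

    def predict_logit(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[0]

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(logit)/d(input) for each sample; dropout off.

        Backpropagates a unit seed through the network, so the result is the
        exact Jacobian row of the scalar log-odds output, per sample.
        """
        x = np.asarray(x, dtype=float)
        _, caches = self._forward(x)
        g = np.ones((x.shape[0], 1))
        for layer in range(3, -1, -1):
            _, da, _ = caches[layer]
            if da is not None:
                g = g * da
            g = g @ self.weights[layer].T
        return g

    def _backward(self, caches, dlogit: np.ndarray):
        """Gradients of the loss wrt weights/biases given d(loss)/d(logit)."""
        gw = [None] * 4
        gb = [None] * 4
        g = dlogit[:, None]
        for layer in range(3, -1, -1):
            h, da, mask = caches[layer]
            if mask is not None:
                g = g * mask
            if da is not None:
                g = g * da
            gw[layer] = h.T @ g
            gb[layer] = g.sum(axis=0)
            if layer > 0:
                g = g @ self.weights[layer].T
        return gw, gb

    # -- training ----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray, seed: int | None = 0) -> "MLP":
        """Minimize BCE + weight decay with Adam; records per-epoch mean loss."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        spec = self.spec
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        step = 0
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, spec.batch_size):
                idx = order[lo:lo + spec.batch_size]
                xb, yb = x[idx], y[idx]
                logits, caches = self._forward(xb, rng=rng)
                # stable BCE-with-logits
                loss = np.mean(
                    np.maximum(logits, 0) - logits * yb + np.log1p(np.exp(-np.abs(logits)))
                )
                epoch_loss += loss * idx.size
                dlogit = (expit(logits) - yb) / idx.size
                gw, gb = self._backward(caches, dlogit)
                step += 1
                lr_t = spec.learning_rate * np.sqrt(
                    1 - spec.adam_beta2**step
                ) / (1 - spec.adam_beta1**step)
                for layer in range(4):
                    g = gw[layer] + 2.0 * spec.weight_decay * self.weights[layer]
                    m_w[layer] = spec.adam_beta1 * m_w[layer] + (1 - spec.adam_beta1) * g
                    v_w[layer] = spec.adam_beta2 * v_w[layer] + (1 - spec.adam_beta2) * g**2
                    self.weights[layer] -= lr_t * m_w[layer] / (
                        np.sqrt(v_w[layer]) + spec.adam_eps
                    )
                    m_b[layer] = spec.adam_beta1 * m_b[layer] + (1 - spec.adam_beta1) * gb[layer]
                    v_b[layer] = spec.adam_beta2 * v_b[layer] + (1 - spec.adam_beta2) * gb[layer] ** 2
                    self.biases[layer] -= lr_t * m_b[layer] / (
                        np.sqrt(v_b[layer]) + spec.adam_eps
                    )
            self.loss_history.append(epoch_loss / n)
        self.trained = True
        return self
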