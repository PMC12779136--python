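"""Minimal dense neural network with manual reverse-mode differentiation.

Built for the WGAN-GP training loop: fully connected layers with LeakyReLU
hidden activations and an optional Tanh output, Adam updates, gradients with
respect to both parameters and inputs, and the second-order term the
gradient penalty needs (the gradient of ``||d critic/d x||`` with respect to
the critic parameters).  For piecewise-linear critics (LeakyReLU hidden
units, linear output) the activation second derivative vanishes almost
everywhere, so the double-backprop implemented here is exact a.e. — the same
value an autodiff framework returns.

Shapes follow the row-major convention: a batch is ``(B, d)``, layer weights
are ``(d_in, d_out)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def leaky_relu(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z >= 0, z, alpha * z)


def leaky_relu_grad(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z >= 0, 1.0, alpha)


@dataclass
class MLP:
    """Dense net: LeakyReLU after every layer except the last; the last layer
    is linear (``output="linear"``) or Tanh (``output="tanh"``)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    leaky_alpha: float = 0.2
    output: str = "linear"

    @classmethod
    def create(
        cls,
        dims: tuple[int, ...],
        rng: np.random.Generator,
        leaky_alpha: float = 0.2,
        output: str = "linear",
    ) -> "MLP":
        """He-style initialization over the layer-width sequence ``dims``."""
        weights, biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / d_in)
            weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            biases.append(np.zeros(d_out))
        return cls(weights=weights, biases=biases, leaky_alpha=leaky_alpha, output=output)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple([self.weights[0].shape[0]] + [w.shape[1] for w in self.weights])

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Forward pass; stores pre-activations/activations when ``cache``
        is a dict (needed for any backward pass)."""
        a = x
        zs, acts = [], [a]
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            zs.append(z)
            last = i == self.n_layers - 1
            if not last:
                a = leaky_relu(z, self.leaky_alpha)
            elif self.output == "tanh":
                a = np.tanh(z)
            else:
                a = z
            acts.append(a)
        if cache is not None:
            cache["zs"], cache["acts"] = zs, acts
        return a

    def _act_grads(self, cache: dict) -> list[np.ndarray]:
        """phi'(z) per layer under the declared activations."""
        grads = []
        for i, z in enumerate(cache["zs"]):
            last = i == self.n_layers - 1
            if not last:
                grads.append(leaky_relu_grad(z, self.leaky_alpha))
            elif self.output == "tanh":
                grads.append(1.0 - np.tanh(z) ** 2)
            else:
                grads.append(np.ones_like(z))
        return grads

    # -- reverse mode -------------------------------------------------------
    def backward(
        self, cache: dict, grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Backprop ``grad_out`` (B x d_out) through the cached forward pass.

        Returns (dW list, db list, grad wrt input).
        """
        phi = self._act_grads(cache)
        acts = cache["acts"]
        dWs = [None] * self.n_layers
        dbs = [None] * self.n_layers
        delta = grad_out * phi[-1]
        for i in range(self.n_layers - 1, -1, -1):
            dWs[i] = acts[i].T @ delta
            dbs[i] = delta.sum(axis=0)
            grad_in = delta @ self.weights[i].T
            if i > 0:
                delta = grad_in * phi[i - 1]
        return dWs, dbs, grad_in

    def input_gradient(self, cache: dict, grad_out: np.ndarray | None = None) -> np.ndarray:
        """Gradient of the (scalar-per-row) output w.r.t. the input batch."""
        if grad_out is None:
            grad_out = np.ones_like(cache["acts"][-1])
        _, _, gx = self.backward(cache, grad_out)
        return gx

    def gradient_norm_param_grads(
        self, cache: dict, r: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Parameter gradients of ``sum_b r_b . grad_x f(x_b)``.

        ``r`` (B x d_in) is the upstream gradient of the loss with respect to
        the per-row input gradient ``g_b = grad_x f(x_b)``.  The directional
        derivative ``h_b = r_b . g_b`` is propagated forward as a tangent
        (t_0 = r, t_i = phi'(z_i) * (t_{i-1} W_i)) and then differentiated in
        reverse.  Treating phi' as locally constant is exact a.e. for
        piecewise-linear activations; biases receive zero gradient.
        """
        if self.output != "linear":
            raise ValueError("second-order penalty is defined for linear-output critics")
        phi = self._act_grads(cache)
        # forward tangent chain
        ts = [r]
        for i in range(self.n_layers):
            s = ts[-1] @ self.weights[i]
            ts.append(phi[i] * s if i < self.n_layers - 1 else s)
        # reverse through the tangent chain; W_i appears exactly once
        dWs = [None] * self.n_layers
        v = np.ones_like(ts[-1])
        for i in range(self.n_layers - 1, -1, -1):
            u = v if i == self.n_layers - 1 else v * phi[i]
            dWs[i] = ts[i].T @ u
            v = u @ self.weights[i].T
        dbs = [np.zeros_like(b) for b in self.biases]
        return dWs, dbs


@dataclass
class Adam:
    """Adam over a list of parameter arrays (updated in place)."""

    params: list[np.ndarray]
    lr: float = 1e-4
    beta1: float = 0.0
    beta2: float = 0.9
    eps: float = 1e-8
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)
    t: int = 0

    def __post_init__(self) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in self.params]
            self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c2 = 1 - b2**self.t
        if not hasattr(self, "_buf"):
            self._buf = [np.empty_like(p) for p in self.params]
        for i, (p, g, v) in enumerate(zip(self.params, grads, self.v)):
            buf = self._buf[i]
            np.square(g, out=buf)
            v *= b2
            buf *= 1 - b2
            v += buf
            np.divide(v, c2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            if b1 == 0.0:  # first moment reduces to the raw gradient
                np.divide(g, buf, out=buf)
            else:
                m = self.m[i]
                m *= b1
                m += (1 - b1) * g
                np.divide(m / (1 - b1**self.t), buf, out=buf)
            buf *= self.lr
            p -= buf
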