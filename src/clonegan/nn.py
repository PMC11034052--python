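"""Minimal feed-forward neural network layer with hand-written backprop.

Implements exactly what the adversarial autoencoder needs: dense layers
with He (fan-in) initialization, LeakyReLU, batch normalization with
running statistics for evaluation mode, a sigmoid output, and the Adam
optimizer.  Everything is float64 NumPy and fully deterministic given the
RNG passed at initialization, which is what makes bit-identical CPU runs
possible.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict
    grads: dict

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine layer y = xW + b with He-normal weight initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        # accumulate: the discriminator update backprops real and fake
        # batches in two passes before one optimizer step
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self.params = {}
        self.grads = {}
        self._mask: np.ndarray | None = None

    def forward(self, x, train):
        out = np.where(x > 0, x, self.slope * x)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def __init__(self):
        self.params = {}
        self.grads = {}
        self._out: np.ndarray | None = None

    def forward(self, x, train):
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class BatchNorm(Layer):
    """Batch normalization over the batch axis.

    Training mode normalizes by batch statistics and updates exponential
    running statistics (momentum 0.1); evaluation mode uses the running
    statistics, so a batch of one encodes identically to the same row
    inside a larger batch.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n), "beta": np.zeros(n)}
        self.grads = {"gamma": np.zeros(n), "beta": np.zeros(n)}
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache: tuple | None = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            x_hat = (x - mean) * inv_std
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            # unbiased variance for the running estimate, as is conventional
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            self._cache = (x_hat, inv_std)
        else:
            x_hat = (x - self.running_mean) / np.sqrt(
                self.running_var + self.eps
            )
        return self.params["gamma"] * x_hat + self.params["beta"]

    def backward(self, grad):
        x_hat, inv_std = self._cache
        n = grad.shape[0]
        self.grads["gamma"] += (grad * x_hat).sum(axis=0)
        self.grads["beta"] += grad.sum(axis=0)
        g = grad * self.params["gamma"]
        # standard batch-norm gradient through the batch statistics
        return inv_std / n * (
            n * g - g.sum(axis=0) - x_hat * (g * x_hat).sum(axis=0)
        )


class MLP:
    """A sequential stack of layers with a joint forward/backward pass."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Backpropagate; accumulates parameter grads, returns input grad."""
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = state[f"{i}.{k}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


def make_mlp(
    sizes: list[int],
    rng: np.random.Generator,
    leaky_slope: float = 0.2,
    batch_norm: bool = True,
    final_activation: str | None = None,
) -> MLP:
    """Build an MLP with LeakyReLU (+ optional BatchNorm) hidden blocks.

    ``sizes`` runs input -> hidden... -> output.  The final layer is linear
    unless ``final_activation`` is ``"sigmoid"``.
    """
    layers: list[Layer] = []
    for i in range(len(sizes) - 1):
        layers.append(Dense(sizes[i], sizes[i + 1], rng))
        last = i == len(sizes) - 2
        if not last:
            if batch_norm:
                layers.append(BatchNorm(sizes[i + 1]))
            layers.append(LeakyReLU(leaky_slope))
        elif final_activation == "sigmoid":
            layers.append(Sigmoid())
        elif final_activation == "leaky_relu":
            layers.append(LeakyReLU(leaky_slope))
    return MLP(layers)


class Adam:
    """Adam optimizer over one or more MLPs."""

    def __init__(
        self,
        nets: list[MLP],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._params = [p for net in nets for p in net.parameters()]
        self._m = [np.zeros_like(l.params[k]) for l, k in self._params]
        self._v = [np.zeros_like(l.params[k]) for l, k in self._params]

    def zero_grad(self) -> None:
        for layer, key in self._params:
            layer.grads[key][...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (layer, key) in enumerate(self._params):
            g = layer.grads[key]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / bc1
            v_hat = self._v[i] / bc2
            layer.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
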