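"""Minimal feed-forward neural network toolkit (numpy).

Implements exactly the pieces the pseudocell models need: dense layers with
ReLU/sigmoid/linear activations, inverted dropout, batch normalization,
the Adam optimizer, and a patience-based early stopper with best-weight
restoration. Everything is driven by an explicit ``numpy.random.Generator``
so that training is bit-reproducible for a fixed seed on a fixed platform.

Gradients for the output nonlinearity + loss pairs (softmax + KL divergence,
sigmoid + binary cross-entropy) are fused in the training loops that use
them; networks here therefore end in a linear layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Dropout",
    "BatchNorm",
    "Sequential",
    "Adam",
    "EarlyStopper",
    "he_init",
    "glorot_init",
]


def he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Kaiming-normal initialization, appropriate for ReLU layers."""
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


def glorot_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Xavier-uniform initialization, for sigmoid/linear layers."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Dense:
    """Fully connected layer ``a = act(x W + b)``.

    Parameters
    ----------
    n_in, n_out:
        Input/output widths.
    activation:
        One of ``"relu"``, ``"sigmoid"``, ``"linear"``.
    rng:
        Generator used for weight initialization.
    """

    #: layers whose weight matrices count toward the L2 penalty
    has_weights = True

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unsupported activation: {activation!r}")
        self.activation = activation
        init = he_init if activation == "relu" else glorot_init
        self.W = init(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._a: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            a = 1.0 / (1.0 + np.exp(-z))
        else:
            a = z
        if training:
            self._x, self._a = x, a
        return a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad = grad * (self._a > 0.0)
        elif self.activation == "sigmoid":
            grad = grad * self._a * (1.0 - self._a)
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Dropout:
    """Inverted dropout; identity at inference time."""

    has_weights = False

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    params: list = []
    grads: list = []


class BatchNorm:
    """Batch normalization with running statistics for inference."""

    has_weights = False  # gamma/beta excluded from the L2 penalty

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = grad.shape[0]
        self.dgamma = (grad * xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        dxhat = grad * self.gamma
        # standard batch-norm backward, vectorized over features
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


class Sequential:
    """Ordered stack of layers with a joint forward/backward pass."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def weight_matrices(self) -> list[np.ndarray]:
        """Weight matrices W_l subject to L2 regularization (biases excluded)."""
        return [layer.W for layer in self.layers if layer.has_weights]

    def l2_penalty(self, lam: float) -> float:
        return lam * sum(float(np.sum(W * W)) for W in self.weight_matrices())

    def add_l2_grads(self, lam: float) -> None:
        """Add the gradient of ``lam * sum ||W||^2`` in place (2*lam*W)."""
        if lam == 0.0:
            return
        for layer in self.layers:
            if layer.has_weights:
                layer.dW += 2.0 * lam * layer.W

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        k = len(self.params)
        for p, s in zip(self.params, state[:k]):
            p[...] = s
        extra = iter(state[k:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adam:
    """Adam optimizer over a fixed list of parameter arrays."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class EarlyStopper:
    """Patience-based early stopping on a monitored validation metric.

    Training stops once the monitored value has not strictly decreased for
    ``patience`` consecutive epochs; the caller then restores the snapshot
    taken at the best epoch. Pure bookkeeping — it can be driven by any
    scripted loss sequence.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_value = np.inf
        self.best_epoch = -1
        self.best_state: list[np.ndarray] | None = None
        self._since_best = 0

    def update(self, epoch: int, value: float, state: list[np.ndarray] | None = None) -> bool:
        """Record one epoch. Returns True when training should stop."""
        if value < self.best_value:
            self.best_value = value
            self.best_epoch = epoch
            self.best_state = state
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience
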