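"""Neural-network building blocks on top of the autodiff core.

Layer composition follows the model's stated order: linear map, ReLU,
batch normalization, dropout.  Normalizing *after* the activation is
unconventional but is the composition the architecture defines; the
conventional order (linear, norm, activation, dropout) is available via
``norm_before_activation``.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "BatchNorm1d", "Dropout", "MLPLayer",
    "Adam", "softmax", "log_softmax", "xavier_uniform", "concat",
]


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    # max-shift is a constant: softmax is shift-invariant, so no grad flows
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


class Module:
    """Parameter container with recursive traversal and train/eval modes."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Module):
                        yield f"{name}.{k}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in = n_in
        self.n_out = n_out
        self.W = Tensor(xavier_uniform(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[-1] != self.n_in:
            raise ValueError(
                f"Linear expected input width {self.n_in}, got {x.data.shape[-1]}")
        return x @ self.W + self.b


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for eval.

    Eval mode always uses running statistics, so inference on a single
    sample is well defined and deterministic.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            xhat = (x - mu) * (var + self.eps) ** -0.5
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            scale = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(self.running_mean)) * Tensor(scale)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout: active in train mode only, identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class MLPLayer(Module):
    """One network layer: linear -> ReLU -> batch-norm -> dropout.

    ``use_activation`` / ``use_batchnorm`` / ``dropout_rate`` toggle the
    stages; ``norm_before_activation`` swaps to the conventional ordering.
    """

    def __init__(self, n_in: int, width: int, rng: np.random.Generator, *,
                 use_activation: bool = True, use_batchnorm: bool = True,
                 dropout_rate: float = 0.0, norm_before_activation: bool = False):
        super().__init__()
        if width <= 0:
            raise ValueError("layer width must be positive")
        self.linear = Linear(n_in, width, rng)
        self.use_activation = use_activation
        self.norm_before_activation = norm_before_activation
        self.bn = BatchNorm1d(width) if use_batchnorm else None
        self.dropout = Dropout(dropout_rate, rng) if dropout_rate > 0 else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.linear(x)
        if self.norm_before_activation:
            if self.bn is not None:
                h = self.bn(h)
            if self.use_activation:
                h = h.relu()
        else:
            if self.use_activation:
                h = h.relu()
            if self.bn is not None:
                h = self.bn(h)
        if self.dropout is not None:
            h = self.dropout(h)
        return h


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
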