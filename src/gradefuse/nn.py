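"""Neural-network layers and optimisation on top of :mod:`gradefuse.autodiff`.

Layers follow the familiar Module convention: parameters are `Tensor`s with
``requires_grad=True`` registered on the module, ``parameters()`` walks the
tree, and an :class:`Adam` optimiser updates them in place.  Every layer takes
an explicit ``rng`` so that initialisation is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv3d, max_pool2d

__all__ = [
    "Module", "Linear", "Conv2d", "Conv3d", "BatchNorm", "Embedding",
    "SelfAttention", "Sequential", "ReLU", "Adam", "cross_entropy",
]


class Module:
    """Base class: registers child modules / parameters via attribute access."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_frozen", False)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        if self._frozen:
            return []
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def freeze(self):
        """Exclude this module's parameters from optimisation."""
        object.__setattr__(self, "_frozen", True)
        return self

    def unfreeze(self):
        object.__setattr__(self, "_frozen", False)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        for k, v in state.items():
            params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, pad=0, bias=True):
        super().__init__()
        self.weight = _param(rng, (c_out, c_in, k, k), c_in * k * k)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Conv3d(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, pad=0, bias=True):
        super().__init__()
        self.weight = _param(rng, (c_out, c_in, k, k, k), c_in * k ** 3)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm(Module):
    """Per-channel normalisation over batch + spatial axes (channel axis 1).

    Uses batch statistics during training and exponential running statistics
    at evaluation time, with a learnable affine.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(a for a in range(x.ndim) if a != 1)
        bshape = tuple(-1 if a == 1 else 1 for a in range(x.ndim))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        # mu/var treated as constants: at desk scale the stop-gradient BN
        # variant is stable and keeps the backward pass simple
        inv = 1.0 / np.sqrt(var + self.eps)
        xn = (x - Tensor(mu.reshape(bshape))) * Tensor(inv.reshape(bshape))
        return xn * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class Embedding(Module):
    def __init__(self, n_classes: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0, 1.0, size=(n_classes, dim)), requires_grad=True)
        self.n_classes = n_classes

    def forward(self, idx) -> Tensor:
        idx = np.asarray(idx, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_classes):
            raise ValueError(f"label out of range [0, {self.n_classes})")
        return self.weight[idx]


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention over a set of vectors.

    No positional encoding: the operator is permutation-equivariant, which is
    the default behaviour for unordered patch sets.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.scale = 1.0 / np.sqrt(dim)

    def forward(self, x: Tensor) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        att = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * self.scale
        return att.softmax(axis=-1) @ v


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between class logits (N, G) and integer labels."""
    labels = np.asarray(labels, dtype=int)
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


class Adam:
    """Adam with decoupled weight decay and an adjustable learning rate."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
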