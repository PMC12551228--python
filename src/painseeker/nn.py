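"""Neural-network layers and the Adam optimizer on the autograd engine.

Layers follow the usual NCHW conventions. Parameter initialisation draws from
a caller-supplied :class:`numpy.random.Generator`, so a model is a pure
function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, maxpool2d


class Module:
    """Base class: child modules/parameters discovered via attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All parameter and buffer arrays keyed by attribute path."""
        out: dict[str, np.ndarray] = {}
        for k, v in vars(self).items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_arrays(prefix=f"{key}.{i}."))
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        mine = self.named_arrays()
        if set(mine) != set(arrays):
            missing = set(mine) ^ set(arrays)
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, arr in arrays.items():
            if mine[k].shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {mine[k].shape} vs {arr.shape}")
            mine[k][...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> None:
        self.training = True
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for v in vars(self).values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()

    training: bool = True


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, 1.0, (out_features, in_features)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.T + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def named_arrays(self, prefix: str = ""):
        out = {f"{prefix}weight": self.weight.data}
        if self.bias is not None:
            out[f"{prefix}bias"] = self.bias.data
        return out

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Composed from autograd primitives; running stats used in eval mode."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with classical (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.weight_decay = lr, weight_decay

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * (p.grad + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
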