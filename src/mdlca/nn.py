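"""Neural-network building blocks over the package's autograd tensors.

Layers follow the usual train/eval-mode semantics: dropout and batch-norm
batch statistics are active only in train mode, and eval-mode forward passes
are fully deterministic.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, conv3d, max_pool3d

__all__ = ["Parameter", "Module", "Sequential", "Linear", "Conv3d",
           "BatchNorm1d", "BatchNorm3d", "Dropout", "AvgPool3d",
           "AdaptiveAvgPool3d", "Adam", "CosineAnnealingLR",
           "he_normal", "xavier_uniform"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_normal(shape: tuple, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def xavier_uniform(shape: tuple, fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: children auto-registered via attribute assignment."""

    def __init__(self):
        self._parameters: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        params = list(self._parameters.values())
        for m in self._modules.values():
            params.extend(m.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + n, p) for n, p in self._parameters.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for name, m in self._modules.items():
            out.extend(m.named_buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buf::" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buf::"):
                name = key[5:]
                if name not in bufs:
                    raise KeyError(f"unknown buffer {name!r}")
                bufs[name][...] = value
            else:
                if key not in params:
                    raise KeyError(f"unknown parameter {key!r}")
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: "
                        f"{params[key].data.shape} vs {value.shape}")
                params[key].data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 init: str = "he", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        if init == "he":
            w = he_normal((in_features, out_features), in_features, rng)
        elif init == "xavier":
            w = xavier_uniform((in_features, out_features), in_features,
                               out_features, rng)
        elif init == "zeros":
            w = np.zeros((in_features, out_features))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"Linear expects last dim {self.in_features}, got {x.shape[-1]}")
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        fan_in = in_channels * kernel ** 3
        self.weight = Parameter(he_normal(
            (out_channels, in_channels, kernel, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)

    def output_side(self, side: int) -> int:
        k = self.weight.shape[2]
        return (side + 2 * self.padding - k) // self.stride + 1


class _BatchNorm(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self._buffers["running_mean"] = np.zeros(num_features)
        self._buffers["running_var"] = np.ones(num_features)

    def _normalize(self, x: Tensor, axes: tuple, shape: tuple) -> Tensor:
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            n = self.momentum
            self._buffers["running_mean"] *= 1 - n
            self._buffers["running_mean"] += n * mean.data.reshape(-1)
            self._buffers["running_var"] *= 1 - n
            self._buffers["running_var"] += n * var.data.reshape(-1)
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(shape)
        b = self.beta.reshape(shape)
        return xhat * g + b


class BatchNorm1d(_BatchNorm):
    """Normalizes (B, C) over the batch axis."""

    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0,), (1, -1))


class BatchNorm3d(_BatchNorm):
    """Normalizes (B, C, D, H, W) over batch and spatial axes."""

    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0, 2, 3, 4), (1, -1, 1, 1, 1))


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class AvgPool3d(Module):
    def __init__(self, kernel: int, stride: int | None = None):
        super().__init__()
        self.kernel = kernel
        self.stride = stride or kernel

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        B, C, D, H, W = x.shape
        Do, Ho, Wo = [(d - k) // s + 1 for d in (D, H, W)]
        # average pooling as a strided view sum; differentiable via conv-free path
        parts = []
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    parts.append(x[:, :, a:a + s * Do:s, b:b + s * Ho:s,
                                   c:c + s * Wo:s])
        out = parts[0]
        for p in parts[1:]:
            out = out + p
        return out * (1.0 / k ** 3)


def _adaptive_pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) averaging matrix with the standard
    floor/ceil window convention (handles n_out greater or less than n_in)."""
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


class AdaptiveAvgPool3d(Module):
    """Pools (B, C, D, H, W) to (B, C, s, s, s) for any target side s."""

    def __init__(self, out_side: int):
        super().__init__()
        self.out_side = out_side

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        s = self.out_side
        for axis, n_in in ((2, D), (3, H), (4, W)):
            mat = Tensor(_adaptive_pool_matrix(n_in, s))
            perm = [0, 1, 2, 3, 4]
            perm.append(perm.pop(axis))
            x = x.transpose(*perm)           # pooled axis last
            x = x @ mat.T
            inv = [0, 1, 2, 3, 4]
            inv.insert(axis, inv.pop(-1))
            x = x.transpose(*inv)
        return x


class MaxPool3d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool3d(x, self.kernel, self.stride, self.padding)

    def output_side(self, side: int) -> int:
        return (side + 2 * self.padding - self.kernel) // self.stride + 1


# -- optimization -------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class CosineAnnealingLR:
    """Cosine decay of the optimizer learning rate over `t_max` epochs."""

    def __init__(self, optimizer: Adam, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = max(t_max, 1)
        self.eta_min = eta_min
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.optimizer.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) \
            * (1 + np.cos(np.pi * frac))
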