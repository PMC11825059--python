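"""Neural-network building blocks on top of the autodiff core.

Conv1d / BatchNorm1d / Linear modules, the three-block residual
time-series encoder architecture, and an Adam optimizer.  Initialization
is fully determined by the ``numpy.random.Generator`` passed in.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batchnorm

__all__ = ["Module", "Conv1d", "BatchNorm1d", "Linear", "Sequential", "ResidualBlock", "Adam"]


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for name, v in self.__dict__.items():
            if name.startswith("_"):  # caches/activations are not parameters
                continue
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for name, v in self.__dict__.items():
            if name.startswith("_"):
                continue
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m._training = True

    def eval(self) -> None:
        for m in self.modules():
            m._training = False

    _training = True

    # ---- flat state dict of plain arrays, for checkpoints and hashing ----
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state length mismatch: {len(own)} vs {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != np.shape(src):
                raise ValueError(f"state shape mismatch: {dst.shape} vs {np.shape(src)}")
            dst[...] = src


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, scale, (out_channels, in_channels, kernel_size)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (N, C, L) or (N, C) inputs.

    Training mode normalizes with batch statistics and updates running
    estimates; eval mode uses the stored running statistics.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2) if x.ndim == 3 else (0,)
        if self._training:
            out, (mu, var) = batchnorm(x, self.gamma, self.beta, axes, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        out, _ = batchnorm(x, self.gamma, self.beta, axes, self.eps,
                           stats=(self.running_mean, self.running_var))
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    """Three conv+BN+ReLU layers with an identity / 1x1-projection shortcut.

    The canonical time-series ResNet block: kernel sizes (k1, k2, k3),
    stride 1 everywhere, so temporal length is preserved.
    """

    def __init__(self, in_channels: int, filters: int, kernel_sizes: tuple[int, int, int],
                 rng: np.random.Generator):
        k1, k2, k3 = kernel_sizes
        self.conv1 = Conv1d(in_channels, filters, k1, rng)
        self.bn1 = BatchNorm1d(filters)
        self.conv2 = Conv1d(filters, filters, k2, rng)
        self.bn2 = BatchNorm1d(filters)
        self.conv3 = Conv1d(filters, filters, k3, rng)
        self.bn3 = BatchNorm1d(filters)
        if in_channels != filters:
            self.shortcut_conv = Conv1d(in_channels, filters, 1, rng)
            self.shortcut_bn = BatchNorm1d(filters)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        if self.shortcut_conv is not None:
            x = self.shortcut_bn(self.shortcut_conv(x))
        return (y + x).relu()


class Adam:
    """Adam with bias correction; state keyed by parameter identity order."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
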