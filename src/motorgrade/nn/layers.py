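"""Layer and module containers built on the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class with recursive named parameter / buffer discovery."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[prefix + name] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{prefix}{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                out[prefix + name] = value
            elif isinstance(value, Module):
                out.update(value.named_buffers(f"{prefix}{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_buffers(f"{prefix}{name}.{i}."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({k: v.copy() for k, v in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self.named_buffers()
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{params[key].data.shape} vs {value.shape}"
                    )
                params[key].data = np.array(value, dtype=np.float64)
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unknown state entry {key}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class PointwiseConv(Module):
    """1x1 convolution across channels (a linear map applied per time step)."""

    def __init__(self, ni: int, no: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_he_normal(rng, (no, ni), ni), requires_grad=True)
        self.bias = Tensor(np.zeros(no), requires_grad=True) if bias else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.pointwise_conv(x, self.weight, self.bias)


class SepConv(Module):
    """Depthwise-separable convolution: per-channel k-tap filter then 1x1 mix."""

    def __init__(self, ni: int, no: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            k += 1
        self.depthwise = Tensor(_he_normal(rng, (ni, k), k), requires_grad=True)
        self.pointwise = PointwiseConv(ni, no, rng, bias=False)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.pointwise(ag.depthwise_conv(x, self.depthwise))


class BatchNorm(Module):
    def __init__(self, c: int):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, training
        )


class XceptionModule(Module):
    """One inception-style module with depthwise-separable branches.

    Four parallel branches on the input: three depthwise-separable
    convolutions at kernel scales {k, k/2, k/4} applied to a pointwise
    bottleneck, plus a maxpool->pointwise branch; outputs concatenated
    to 4*nf channels.
    """

    def __init__(self, ni: int, nf: int, ks: int, rng: np.random.Generator):
        self.bottleneck = PointwiseConv(ni, nf, rng, bias=False)
        kernel_sizes = [ks, ks // 2, ks // 4]
        self.convs = [SepConv(nf, nf, k, rng) for k in kernel_sizes]
        self.pool_conv = PointwiseConv(ni, nf, rng, bias=False)
        self.out_channels = 4 * nf

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        b = self.bottleneck(x)
        branches = [conv(b) for conv in self.convs]
        branches.append(self.pool_conv(ag.maxpool_same(x, 3)))
        return ag.concat(branches, axis=1)


class ResidualShortcut(Module):
    """Pointwise conv + batch norm matching channels for a skip connection."""

    def __init__(self, ni: int, no: int, rng: np.random.Generator):
        self.conv = PointwiseConv(ni, no, rng, bias=False)
        self.bn = BatchNorm(no)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.bn(self.conv(x), training)
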