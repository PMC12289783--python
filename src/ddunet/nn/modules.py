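"""Layer modules: parameter containers with a recursive registry.

Initialization follows common practice for this kind of network: He-normal
for convolution kernels feeding ReLU/Swish, Xavier-uniform for attention
projection matrices.  Every module draws from the ``numpy.random.Generator``
it is handed, so a model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item
            elif isinstance(v, dict):
                for k, item in v.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{k}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{k}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        # parameters plus batchnorm running buffers, keyed by attribute path
        def walk(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, BatchNorm2d):
                    state[f"{key}.running_mean"] = v.running_mean.copy()
                    state[f"{key}.running_var"] = v.running_var.copy()
                if isinstance(v, Module):
                    walk(v, f"{key}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                elif isinstance(v, dict):
                    for k, item in v.items():
                        if isinstance(item, Module):
                            walk(item, f"{key}.{k}.")

        state = {name: p.data.copy() for name, p in self.named_parameters()}
        walk(self, "")
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=np.float64)

        def walk(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, BatchNorm2d):
                    v.running_mean = np.array(state[f"{key}.running_mean"])
                    v.running_var = np.array(state[f"{key}.running_var"])
                if isinstance(v, Module):
                    walk(v, f"{key}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                elif isinstance(v, dict):
                    for k, item in v.items():
                        if isinstance(item, Module):
                            walk(item, f"{key}.{k}.")

        walk(self, "")


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def xavier_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=None, bias=True):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = cin * k * k
        self.weight = Parameter(he_normal(rng, (cout, cin, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseSeparableConv(Module):
    """3x3 depthwise filter followed by a 1x1 pointwise mix."""

    def __init__(self, cin, cout, rng, k=3):
        super().__init__()
        self.dw_weight = Parameter(he_normal(rng, (cin, 1, k, k), k * k))
        self.padding = k // 2
        self.pw = Conv2d(cin, cout, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = F.conv2d(x, self.dw_weight, None, 1, self.padding, depthwise=True)
        return self.pw(x)


class ConvTranspose2x(Module):
    """Learned x2 deconvolution: zero-insertion then a 2x2 convolution."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (cout, cin, 2, 2), cin * 4))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        x = F.dilate2d(x, 2)          # [.., 2H-1, 2W-1]
        x = x.pad2d((1, 1, 1, 1))     # full padding for the 2x2 kernel
        return F.conv2d(x, self.weight, self.bias, 1, 0)  # -> [.., 2H, 2W]


class BatchNorm2d(Module):
    def __init__(self, c, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, din, dout, rng, bias=True):
        super().__init__()
        self.weight = Parameter(xavier_uniform(rng, (din, dout)))
        self.bias = Parameter(np.zeros(dout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout; draws its masks from a dedicated generator so the
    training stream is reproducible from one seed."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation, the encoder/decoder workhorse."""

    def __init__(self, cin, cout, k, rng, act: str = "relu"):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv(x))
        return x.relu() if self.act == "relu" else x.swish()
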