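"""Neural-network building blocks on top of the autodiff engine.

Modules mirror the familiar torch.nn surface (Conv2d, Linear, BatchNorm2d,
Sequential) at the scale this package needs.  All parameter initialisation
is driven by an explicit ``numpy.random.Generator`` so two builds from the
same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat (de)serialisation -------------------------------------------
    def state_arrays(self):
        """All learnable parameters and buffers in a stable order."""
        out = list(self.parameters())
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean, m.running_var])
        return out

    def state_dict(self) -> dict:
        return {f"a{i}": np.asarray(a.data if isinstance(a, Tensor) else a)
                for i, a in enumerate(self.state_arrays())}

    def load_state_dict(self, d: dict):
        arrays = self.state_arrays()
        if len(arrays) != len(d):
            raise ValueError("checkpoint does not match model architecture")
        for i, a in enumerate(arrays):
            new = np.asarray(d[f"a{i}"], dtype=np.float64)
            if isinstance(a, Tensor):
                if a.data.shape != new.shape:
                    raise ValueError("checkpoint tensor shape mismatch")
                a.data = new.copy()
            else:  # raw buffer ndarray: copy in place
                a[...] = new

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=None, groups=1,
                 bias=True):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (cin // groups) * k * k
        self.weight = Parameter(_he_normal(rng, (cout, cin // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, cin, cout, rng, bias=True):
        super().__init__()
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(1.0 / cin), size=(cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            out, mu, var = ad.batchnorm2d(x, self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
            return out
        sh = (1, -1, 1, 1)
        sd = np.sqrt(self.running_var.reshape(sh) + self.eps)
        scale = (self.weight.data / sd.ravel()).reshape(sh).astype(ad.DTYPE)
        shift = (self.bias.data - self.running_mean * self.weight.data
                 / sd.ravel()).reshape(sh).astype(ad.DTYPE)
        return ad.astensor(x) * scale + shift


class ConvBNRelu(Module):
    def __init__(self, cin, cout, k, rng, stride=1, groups=1):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, groups=groups,
                           bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class Adam:
    """Adam optimiser with optional step-wise learning-rate updates."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.99), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
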