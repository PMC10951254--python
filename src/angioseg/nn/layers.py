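"""Layer modules: containers, convolution, batch norm, linear, SE attention."""
from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor, relu, sigmoid


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class; children are discovered through instance attributes."""

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, c in self._children():
            yield from c.modules()

    # -- mode / state -----------------------------------------------------
    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32)
        for name, m in self._named_modules():
            for bname in getattr(m, "_buffers", {}):
                key = f"{name}{bname}"
                if key in state:
                    m._buffers[bname] = np.asarray(state[key], dtype=np.float32)
                    setattr(m, bname, m._buffers[bname])

    def _named_modules(self, prefix=""):
        yield prefix, self
        for name, c in self._children():
            yield from c._named_modules(prefix + name + ".")

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        if isinstance(x, F.Probe):
            return x
        return relu(x)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must divide groups")
        rng = rng or np.random.default_rng()
        fan_in = cin // groups * k * k
        bound = math.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, bound, size=(cout, cin // groups, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        if isinstance(x, F.Probe):
            x.counter["params"] += self.weight.data.size + (
                self.bias.data.size if self.bias is not None else 0)
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(1.0 / cin)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(cout, cin)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        if isinstance(x, F.Probe):
            x.counter["params"] += self.weight.data.size + (
                self.bias.data.size if self.bias is not None else 0)
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel with running statistics."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._buffers = {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        if isinstance(x, F.Probe):
            x.counter["params"] += self.gamma.data.size + self.beta.data.size
            return x
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / x.shape[1]
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Global average pool -> Linear(C, C/r) -> ReLU -> Linear(C/r, C) ->
    sigmoid, then channel-wise rescaling of the input. The bottleneck width
    is rounded up to at least 1 when r does not divide C.
    """

    def __init__(self, c, reduction=16, hidden=None, rng=None):
        super().__init__()
        if hidden is None:
            hidden = max(1, int(math.ceil(c / reduction)))
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)
        self.c = c

    def forward(self, x):
        if isinstance(x, F.Probe):
            g = F.global_avg_pool(x)
            g = self.fc1(g)
            g = self.fc2(g)
            return x.spawn(x.shape)
        g = F.global_avg_pool(x)                  # (N, C)
        g = relu(self.fc1(g))
        g = sigmoid(self.fc2(g))
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1)
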