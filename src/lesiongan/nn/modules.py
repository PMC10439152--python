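"""Layer abstractions over the autograd core.

Mirrors the familiar Module/Parameter idiom: modules register parameters and
sub-modules on attribute assignment, expose ``parameters()`` /
``state_dict()``, and carry a train/eval flag that batch normalization
consults.  Initialization draws from a module-level generator reseeded via
:func:`seed` so that network construction is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, conv2d

__all__ = [
    "seed",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Swish",
    "ReLU",
    "Sigmoid",
]

_rng = np.random.default_rng(0)


def seed(n: int) -> None:
    """Reseed the generator used for parameter initialization."""
    global _rng
    _rng = np.random.default_rng(int(n))


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self):
        for mprefix, mod in self.named_modules():
            for pname, p in mod._params.items():
                yield (f"{mprefix}.{pname}" if mprefix else pname), p

    def parameters(self) -> list[Parameter]:
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def parameter_count(self) -> int:
        """Number of trainable scalars (buffers excluded)."""
        return sum(p.data.size for p in self.parameters())

    # -- mode ---------------------------------------------------------------
    def train(self, mode: bool = True):
        for _, mod in self.named_modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for mprefix, mod in self.named_modules():
            for pname, p in mod._params.items():
                state[f"{mprefix}.{pname}" if mprefix else pname] = p.data
            for bname, b in mod._buffers.items():
                state[f"{mprefix}.{bname}" if mprefix else bname] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}")
        for mprefix, mod in self.named_modules():
            for pname, p in mod._params.items():
                key = f"{mprefix}.{pname}" if mprefix else pname
                if p.data.shape != state[key].shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.asarray(state[key], dtype=np.float32).copy()
            for bname in list(mod._buffers):
                key = f"{mprefix}.{bname}" if mprefix else bname
                mod.register_buffer(bname, np.asarray(state[key]).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)


class Conv2d(Module):
    """2-D convolution with fan-in-scaled normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride=1, padding=0,
                 dilation=1, groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        fan_in = (in_ch // groups) * kh * kw
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(_rng.normal(0.0, std, size=(out_ch, in_ch // groups, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            xhat = centered * ((var + self.eps) ** -0.5)
            m = self.momentum
            self.register_buffer(
                "running_mean",
                ((1 - m) * self.running_mean + m * mu.data.reshape(-1)).astype(np.float32),
            )
            self.register_buffer(
                "running_var",
                ((1 - m) * self.running_var + m * var.data.reshape(-1)).astype(np.float32),
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.swish()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
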