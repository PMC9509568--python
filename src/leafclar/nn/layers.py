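"""Layer/module system: parameter containers over :mod:`leafclar.nn.ops`."""

from __future__ import annotations

import json

import numpy as np

from . import ops
from .tensor import Tensor


class Module:
    """Base class: tracks child modules, parameters and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor):
            self._params[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal ---------------------------------------------------------
    def named_modules(self, prefix=""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode --------------------------------------------------------------
    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for name, p in self.named_parameters():
            state[name] = p.data
        for mname, mod in self.named_modules():
            for bname, buf in mod._buffers.items():
                state[(f"{mname}.{bname}" if mname else bname)] = buf
        return state

    def load_state_dict(self, state: dict) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"missing keys in state: {sorted(missing)[:5]} ...")
        for name, p in self.named_parameters():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()
        for mname, mod in self.named_modules():
            for bname in mod._buffers:
                key = f"{mname}.{bname}" if mname else bname
                arr = np.asarray(state[key])
                mod._buffers[bname][...] = arr
        return None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self._list = []
        for m in modules:
            setattr(self, str(len(self._list)), m)
            self._list.append(m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.weight = Tensor(np.zeros((out_ch, in_ch, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def reset_parameters(self, rng: np.random.Generator):
        fan_in = self.in_ch * self.kernel ** 2
        std = np.sqrt(2.0 / fan_in)
        self.weight.data = rng.normal(0.0, std, self.weight.data.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data = np.zeros(self.out_ch, dtype=np.float32)

    def forward(self, x):
        return ops.conv2d(x, self.weight, self.bias,
                          stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 init_std: float | None = None):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.init_std = init_std  # classifier heads start near zero logits
        self.weight = Tensor(np.zeros((out_features, in_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def reset_parameters(self, rng: np.random.Generator):
        std = self.init_std if self.init_std is not None \
            else np.sqrt(2.0 / self.in_features)
        self.weight.data = rng.normal(0.0, std, self.weight.data.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data = np.zeros(self.out_features, dtype=np.float32)

    def forward(self, x):
        return ops.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 zero_init: bool = False):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.zero_init = zero_init  # residual-branch trick: start as identity-free path
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))

    def reset_parameters(self, rng: np.random.Generator):
        self.gamma.data = np.zeros(self.ch, dtype=np.float32) if self.zero_init \
            else np.ones(self.ch, dtype=np.float32)
        self.beta.data = np.zeros(self.ch, dtype=np.float32)
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x):
        return ops.batch_norm(x, self.gamma, self.beta,
                              self.running_mean, self.running_var,
                              self.training, self.momentum, self.eps)


class BatchNorm1d(BatchNorm2d):
    """Batch normalization over (B, C) descriptors; same parameters/buffers."""


class Activation(Module):
    """'elu' (default) or 'relu'; the backbone swaps these for ablations."""

    def __init__(self, kind: str = "elu", alpha: float = 1.0):
        super().__init__()
        if kind not in ("elu", "relu"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind, self.alpha = kind, alpha

    def forward(self, x):
        return ops.elu(x, self.alpha) if self.kind == "elu" else ops.relu(x)


def init_parameters(module: Module, seed: int) -> Module:
    """Deterministically He-initialize every layer (insertion order)."""
    rng = np.random.default_rng(seed)
    for _, m in module.named_modules():
        reset = getattr(m, "reset_parameters", None)
        if reset is not None:
            reset(rng)
    return module


def save_checkpoint(path, module: Module, config: dict) -> None:
    state = {k.replace(".", "/"): v for k, v in module.state_dict().items()}
    state["__config__"] = np.frombuffer(
        json.dumps(config, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, module: Module, expected_config: dict | None = None) -> dict:
    with np.load(path) as npz:
        config = json.loads(bytes(npz["__config__"].tobytes()).decode())
        state = {k.replace("/", "."): npz[k] for k in npz.files if k != "__config__"}
    if expected_config is not None:
        mismatches = {k for k in expected_config
                      if json.dumps(expected_config[k]) != json.dumps(config.get(k))}
        if mismatches:
            raise ValueError(f"checkpoint config mismatch on {sorted(mismatches)}")
    module.load_state_dict(state)
    return config
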