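"""Minimal neural-network layers and optimizers over the autodiff engine.

Layers follow the conventions of mainstream CNN frameworks (NCHW layout,
He-style initialization for convolutions). Two features matter for the
search engine and are worth calling out:

* **Functional parameter override.** Every forward method accepts an
  optional ``params`` mapping ``id(original parameter) -> replacement
  Tensor``. Passing the result of a differentiable one-step update lets the
  same network be evaluated at "virtual" weights E' or W' while keeping the
  whole computation on the tape — the mechanism behind unrolled
  hypergradients.
* **Batch-norm statistics gating.** Running statistics are mutated only when
  the global flag set by :func:`bn_stats_frozen` allows it, so probe and
  unrolled passes leave the model state untouched.
"""

from __future__ import annotations

import contextlib
import math
import threading
from typing import Mapping, Optional, Sequence

import numpy as np

from .autograd import (
    Tensor,
    broadcast_to,
    clip,
    concat,
    div,
    exp,
    getitem,
    log,
    log_softmax,
    matmul,
    mean,
    mul,
    no_grad,
    power,
    relu,
    reshape,
    softmax,
    sqrt,
    sub,
    tmax,
    transpose,
    tsum,
    unfold,
)

_bn_state = threading.local()


def _bn_updates_enabled() -> bool:
    return getattr(_bn_state, "enabled", True)


@contextlib.contextmanager
def bn_stats_frozen():
    """Freeze batch-norm running statistics inside the block."""
    prev = _bn_updates_enabled()
    _bn_state.enabled = False
    try:
        yield
    finally:
        _bn_state.enabled = prev


def _get(params: Optional[Mapping[int, Tensor]], p: Tensor) -> Tensor:
    if params is None:
        return p
    return params.get(id(p), p)


class Module:
    """Base class: tracks sub-modules and parameters in definition order."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def forward(self, x, params=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, params=None):
        return self.forward(x, params=params)

    # -- flat-state serialization ----------------------------------------
    def state_arrays(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.mean"] = m.running_mean.copy()
                state[f"__bn{i}.var"] = m.running_var.copy()
        return state

    def load_state_arrays(self, state: dict):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{i}.mean"].copy()
                m.running_var = state[f"__bn{i}.var"].copy()


class ModuleList(Module):
    def __init__(self, mods: Sequence[Module] = ()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x, params=None):
        for m in self.layers:
            x = m(x, params=params)
        return x


def _param(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    std = math.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    """2-D convolution (im2col + matmul), with optional dilation and groups.

    Only the two group settings the cell operations use are supported:
    ``groups=1`` (dense) and ``groups=in_channels`` (depthwise).
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, dilation=1,
                 groups=1, bias=False, rng=None, dtype=np.float32):
        super().__init__()
        self.depthwise = groups != 1
        if self.depthwise and groups != in_ch:
            raise ValueError("Conv2d supports groups=1 or depthwise groups only")
        if self.depthwise and out_ch != in_ch:
            raise ValueError("depthwise Conv2d requires out_ch == in_ch")
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        kh, kw = self.kernel
        if not self.depthwise:
            self.weight = _param(rng, (out_ch, in_ch * kh * kw), in_ch * kh * kw, dtype)
        else:
            self.weight = _param(rng, (in_ch, kh * kw), kh * kw, dtype)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x, params=None):
        w = _get(params, self.weight)
        n = x.shape[0]
        kh, kw = self.kernel
        cols = unfold(x, self.kernel, self.stride, self.padding, self.dilation)
        oh_ow = cols.shape[-1]
        h_out = (x.shape[2] + 2 * self.padding - ((kh - 1) * self.dilation + 1)) // self.stride + 1
        w_out = oh_ow // h_out
        if not self.depthwise:
            out = matmul(w, cols)  # [N, out_ch, L] via broadcasting
        else:
            cols = reshape(cols, (n, self.in_ch, kh * kw, oh_ow))
            out = tsum(mul(cols, reshape(w, (1, self.in_ch, kh * kw, 1))), axis=2)
        out = reshape(out, (n, self.out_ch, h_out, w_out))
        if self.bias is not None:
            b = _get(params, self.bias)
            out = out + reshape(b, (1, self.out_ch, 1, 1))
        return out


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_f)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_f, out_f)).astype(dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x, params=None):
        out = matmul(x, _get(params, self.weight))
        if self.bias is not None:
            out = out + _get(params, self.bias)
        return out


class BatchNorm2d(Module):
    """Batch normalization over N,H,W with optional affine transform.

    Training mode normalizes with batch statistics (kept on the tape so the
    layer is differentiable through unrolled steps); eval mode uses running
    statistics. Running statistics are frozen inside probe passes, see
    :func:`bn_stats_frozen`.
    """

    def __init__(self, ch, affine=True, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.affine = affine
        if affine:
            self.weight = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
            self.bias = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def forward(self, x, params=None):
        if self.training:
            mu = mean(x, axis=(0, 2, 3), keepdims=True)
            xc = sub(x, mu)
            var = mean(mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            if _bn_updates_enabled():
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
                self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = div(xc, sqrt(var + self.eps))
        else:
            mu = self.running_mean.reshape(1, self.ch, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, self.ch, 1, 1)
            xhat = div(sub(x, Tensor(mu.astype(x.dtype))), Tensor(sd.astype(x.dtype)))
        if self.affine:
            w = reshape(_get(params, self.weight), (1, self.ch, 1, 1))
            b = reshape(_get(params, self.bias), (1, self.ch, 1, 1))
            xhat = mul(xhat, w) + b
        return xhat


class ReLU(Module):
    def forward(self, x, params=None):
        return relu(x)


def max_pool2d(x, kernel: int = 3, stride: int = 1, padding: int = 1) -> Tensor:
    n, c = x.shape[0], x.shape[1]
    cols = unfold(x, (kernel, kernel), stride, padding)
    l = cols.shape[-1]
    h_out = (x.shape[2] + 2 * padding - kernel) // stride + 1
    cols = reshape(cols, (n, c, kernel * kernel, l))
    # padded entries are zeros; for strictly correct max pooling of arbitrary
    # inputs they should be -inf, but all cell inputs pass through BN/ReLU so
    # a zero floor at the border matches common supernet implementations
    out = tmax(cols, axis=2)
    return reshape(out, (n, c, h_out, l // h_out))


def avg_pool2d(x, kernel: int = 3, stride: int = 1, padding: int = 1) -> Tensor:
    n, c = x.shape[0], x.shape[1]
    cols = unfold(x, (kernel, kernel), stride, padding)
    l = cols.shape[-1]
    h_out = (x.shape[2] + 2 * padding - kernel) // stride + 1
    cols = reshape(cols, (n, c, kernel * kernel, l))
    out = mean(cols, axis=2)  # count_include_pad, as in the reference cells
    return reshape(out, (n, c, h_out, l // h_out))


def global_avg_pool(x) -> Tensor:
    return mean(x, axis=(2, 3))


def one_hot(labels: np.ndarray, num_classes: int, dtype=np.float64) -> np.ndarray:
    eye = np.eye(num_classes, dtype=dtype)
    return eye[np.asarray(labels, dtype=np.int64)]


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against raw logits."""
    k = logits.shape[-1]
    target = Tensor(one_hot(labels, k, dtype=logits.dtype))
    return mean(-tsum(mul(target, log_softmax(logits, axis=-1)), axis=-1))


def soft_cross_entropy(logits: Tensor, target_probs: Tensor) -> Tensor:
    """Mean of -sum(b * log softmax(z)) with a (possibly on-tape) soft target."""
    return mean(-tsum(mul(target_probs, log_softmax(logits, axis=-1)), axis=-1))


# ---------------------------------------------------------------------------
# optimizers (operate on raw .data / .grad outside any tape)
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, params, lr, momentum=0.0, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [None] * len(self.params)

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                if self._buf[i] is None:
                    self._buf[i] = np.array(g, dtype=p.data.dtype)
                else:
                    self._buf[i] = self.momentum * self._buf[i] + g
                g = self._buf[i]
            p.data = p.data - self.lr * g

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr=3e-4, betas=(0.5, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self._t)
            vhat = self._v[i] / (1 - b2 ** self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, epoch: int, total_epochs: int, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate for the given (0-based) epoch."""
    if total_epochs <= 1:
        return base_lr
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (base_lr - lr_min) * (1 + math.cos(math.pi * t))
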