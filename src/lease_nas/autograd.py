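"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the package: a small define-by-run tape with
support for *higher-order* derivatives. Every primitive's vector-Jacobian
product (VJP) is itself expressed in terms of primitives, so gradients can be
re-differentiated (``create_graph=True``), which is what the unrolled
one-step hypergradients of the search engine require.

Design notes
------------
* A :class:`Tensor` wraps an ``np.ndarray``; an operation whose inputs do not
  require gradients records nothing, so inference passes build no graph.
* ``grad(output, inputs, create_graph=...)`` mirrors the semantics of the
  corresponding routine in mainstream autodiff frameworks: it returns the
  gradients as Tensors and, when ``create_graph`` is set, the returned
  gradients are themselves differentiable.
* Data-dependent but locally-constant quantities (argmax masks, clip masks,
  one-hot selections) are treated as constants of the linearization; this is
  the standard almost-everywhere derivative for piecewise-linear primitives.
"""

from __future__ import annotations

import contextlib
import threading

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "add",
    "sub",
    "mul",
    "neg",
    "div",
    "power",
    "exp",
    "log",
    "matmul",
    "tsum",
    "tmax",
    "mean",
    "reshape",
    "transpose",
    "broadcast_to",
    "relu",
    "clip",
    "getitem",
    "concat",
    "unfold",
    "fold",
    "softmax",
    "log_softmax",
    "sqrt",
]

_state = threading.local()


def _grad_enabled() -> bool:
    return getattr(_state, "grad_enabled", True)


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    prev = _grad_enabled()
    _state.grad_enabled = False
    try:
        yield
    finally:
        _state.grad_enabled = prev


class Tensor:
    """A NumPy array plus the tape metadata needed for reverse mode."""

    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        # sequence of (parent Tensor, vjp callable Tensor -> Tensor)
        self._parents = _parents

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self):
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        flag = ", requires_grad=True" if self.requires_grad else ""
        return f"Tensor(shape={self.shape}, dtype={self.dtype}{flag})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def backward(self, grad_output=None):
        """Accumulate gradients into ``.grad`` (NumPy arrays) of leaf tensors."""
        leaves = _all_leaves(self)
        gs = grad(self, leaves, grad_output=grad_output, create_graph=False)
        for leaf, g in zip(leaves, gs):
            if g is None:
                continue
            if leaf.grad is None:
                leaf.grad = g.data.copy()
            else:
                leaf.grad = leaf.grad + g.data


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def _make(data, parents):
    """Create an op output, recording parents only when grad is flowing."""
    if _grad_enabled():
        parents = tuple(p for p in parents if p[0].requires_grad)
        if parents:
            return Tensor(data, requires_grad=True, _parents=parents)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------


def _sum_to(g: Tensor, shape) -> Tensor:
    """Reduce ``g`` (result of broadcasting) back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    nd_extra = g.ndim - len(shape)
    if nd_extra > 0:
        g = tsum(g, axis=tuple(range(nd_extra)), keepdims=False)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------


def _coerce(a, b):
    """Convert operands to Tensors; Python scalars adopt the array dtype
    (preventing silent float64 promotion of float32 graphs)."""
    if isinstance(a, Tensor):
        if isinstance(b, Tensor):
            return a, b
        return a, Tensor(np.asarray(b, dtype=a.dtype))
    if isinstance(b, Tensor):
        return Tensor(np.asarray(a, dtype=b.dtype)), b
    return as_tensor(a), as_tensor(b)


def add(a, b) -> Tensor:
    a, b = _coerce(a, b)
    out = a.data + b.data
    return _make(
        out,
        [
            (a, lambda g, sa=a.shape: _sum_to(g, sa)),
            (b, lambda g, sb=b.shape: _sum_to(g, sb)),
        ],
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = _coerce(a, b)
    out = a.data * b.data
    return _make(
        out,
        [
            (a, lambda g, o=b, sa=a.shape: _sum_to(mul(g, o), sa)),
            (b, lambda g, o=a, sb=b.shape: _sum_to(mul(g, o), sb)),
        ],
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    c = float(exponent)
    out = (a.data ** c).astype(a.dtype, copy=False)
    return _make(out, [(a, lambda g: mul(g, mul(c, power(a, c - 1.0))))])


def div(a, b) -> Tensor:
    return mul(a, power(b, -1.0))


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    # the vjp recomputes exp(a) rather than capturing the output tensor,
    # which would create a reference cycle pinning whole graphs in memory
    return _make(np.exp(a.data), [(a, lambda g: mul(g, exp(a)))])


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def vjp_a(g):
        r = matmul(g, _swap_last(b))
        return _sum_to(r, a.shape) if r.shape != a.shape else r

    def vjp_b(g):
        r = matmul(_swap_last(a), g)
        return _sum_to(r, b.shape) if r.shape != b.shape else r

    return _make(out, [(a, vjp_a), (b, vjp_b)])


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, tuple(axes))


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            kshape = list(a.shape)
            for ax in axes:
                kshape[ax % a.ndim] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.shape)

    return _make(out, [(a, vjp)])


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.max(axis=axis, keepdims=keepdims)
    # one-hot mask of (first-occurring) maxima: constant of the linearization
    expanded = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == expanded)
    if axis is not None:
        # break ties toward the first index, as argmax would
        cum = np.cumsum(mask, axis=axis)
        mask = mask & (cum == 1)
    else:
        flat = mask.ravel()
        first = np.argmax(flat)
        m = np.zeros_like(flat)
        m[first] = True
        mask = m.reshape(mask.shape)
    mask = mask.astype(a.dtype)

    def vjp(g):
        if axis is None:
            g = reshape(g, (1,) * a.ndim)
        elif not keepdims:
            kshape = list(a.shape)
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            for ax in axes:
                kshape[ax % a.ndim] = 1
            g = reshape(g, tuple(kshape))
        return mul(broadcast_to(g, a.shape), Tensor(mask))

    return _make(out, [(a, vjp)])


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    out = np.broadcast_to(a.data, shape)
    return _make(np.ascontiguousarray(out), [(a, lambda g: _sum_to(g, a.shape))])


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = (a.data > 0).astype(a.dtype)
    return _make(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp to [lo, hi]; gradient is the indicator of the interior."""
    a = as_tensor(a)
    mask = ((a.data > lo) & (a.data < hi)).astype(a.dtype)
    return _make(np.clip(a.data, lo, hi), [(a, lambda g: mul(g, Tensor(mask)))])


# ---------------------------------------------------------------------------
# indexing / concatenation
# ---------------------------------------------------------------------------


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out = a.data[idx]

    def vjp(g):
        return _scatter(g, idx, a.shape)

    return _make(out, [(a, vjp)])


def _scatter(g: Tensor, idx, shape) -> Tensor:
    """Adjoint of basic slicing: place ``g`` into zeros of ``shape``."""
    g = as_tensor(g)
    out = np.zeros(shape, dtype=g.dtype)
    out[idx] = g.data

    def vjp(gg):
        return getitem(gg, idx)

    return _make(out, [(g, vjp)])


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])

    parents = []
    for i, t in enumerate(tensors):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        parents.append((t, lambda g, sl=tuple(sl): getitem(g, sl)))
    return _make(out, parents)


# ---------------------------------------------------------------------------
# im2col / col2im — the linear pair behind all convolutions and pooling
# ---------------------------------------------------------------------------

def _unfold_params(x_shape, kernel, stride, padding, dilation):
    n, c, h, w = x_shape
    kh, kw = kernel
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    oh = (h + 2 * padding - eff_kh) // stride + 1
    ow = (w + 2 * padding - eff_kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError(
            f"unfold: kernel {kernel} (dilation {dilation}) does not fit "
            f"input {h}x{w} with padding {padding}"
        )
    return oh, ow


def _unfold_data(x: np.ndarray, kernel, stride, padding, dilation) -> np.ndarray:
    n, c, h, w = x.shape
    kh, kw = kernel
    oh, ow = _unfold_params(x.shape, kernel, stride, padding, dilation)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    sn, sc, sh, sw = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh * dilation, sw * dilation, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, oh * ow)


def _fold_data(cols: np.ndarray, out_shape, kernel, stride, padding, dilation):
    """Adjoint of ``_unfold_data``: scatter-add columns back to an image.

    Implemented as one strided slice-add per kernel offset (kh*kw adds),
    which is far cheaper than an elementwise scatter.
    """
    n = cols.shape[0]
    c, h, w = out_shape
    kh, kw = kernel
    oh, ow = _unfold_params((n, c, h, w), kernel, stride, padding, dilation)
    hp, wp = h + 2 * padding, w + 2 * padding
    buf = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    src = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        r0 = i * dilation
        for j in range(kw):
            c0 = j * dilation
            buf[:, :, r0 : r0 + oh * stride : stride,
                c0 : c0 + ow * stride : stride] += src[:, :, i, j]
    if padding:
        buf = buf[:, :, padding : padding + h, padding : padding + w]
        return np.ascontiguousarray(buf)
    return buf


def unfold(x, kernel, stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Extract sliding patches: [N,C,H,W] -> [N, C*kh*kw, OH*OW]."""
    x = as_tensor(x)
    kernel = tuple(kernel)
    out = _unfold_data(x.data, kernel, stride, padding, dilation)
    spatial = x.shape[1:]

    def vjp(g):
        return fold(g, spatial, kernel, stride, padding, dilation)

    return _make(out, [(x, vjp)])


def fold(cols, out_shape, kernel, stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Adjoint of :func:`unfold` (scatter-add patches into an image)."""
    cols = as_tensor(cols)
    kernel = tuple(kernel)
    out_shape = tuple(out_shape)
    out = _fold_data(cols.data, out_shape, kernel, stride, padding, dilation)

    def vjp(g):
        return unfold(g, kernel, stride, padding, dilation)

    return _make(out, [(cols, vjp)])


# ---------------------------------------------------------------------------
# softmax family (numerically stable; the shift is detached, which leaves the
# analytic derivative unchanged)
# ---------------------------------------------------------------------------


def log_softmax(z, axis: int = -1) -> Tensor:
    z = as_tensor(z)
    shift = Tensor(z.data.max(axis=axis, keepdims=True))
    zs = sub(z, shift)
    return sub(zs, log(tsum(exp(zs), axis=axis, keepdims=True)))


def softmax(z, axis: int = -1) -> Tensor:
    z = as_tensor(z)
    shift = Tensor(z.data.max(axis=axis, keepdims=True))
    e = exp(sub(z, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# the reverse pass
# ---------------------------------------------------------------------------


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if parent.requires_grad and id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def _all_leaves(root: Tensor):
    return [t for t in _toposort(root) if t.requires_grad and not t._parents]


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of ``output`` w.r.t. ``inputs``.

    Returns a list of Tensors aligned with ``inputs``; entries are ``None``
    where the output does not depend on the input. With ``create_graph`` the
    returned gradients carry their own tape and can be differentiated again.
    """
    if not isinstance(inputs, (list, tuple)):
        inputs = [inputs]
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    elif not isinstance(grad_output, Tensor):
        grad_output = Tensor(np.asarray(grad_output, dtype=output.dtype))

    order = _toposort(output)
    grads = {id(output): grad_output}
    input_ids = {id(t) for t in inputs}

    # restrict the sweep to nodes lying on a path from the output to some
    # requested input: big graphs (e.g. differentiating an inner attack step
    # w.r.t. its perturbation only) would otherwise be swept in full
    relevant = set()
    for node in order:  # parents before children
        nid = id(node)
        if nid in input_ids or any(id(p) in relevant for p, _ in node._parents):
            relevant.add(nid)

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node._parents:
                if id(parent) not in relevant:
                    continue
                pg = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = pg if prev is None else add(prev, pg)
            if id(node) in input_ids:
                grads[id(node)] = g  # keep for result extraction

    results = []
    for t in inputs:
        g = grads.get(id(t))
        results.append(g)
    return results
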