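"""Cell-based differentiable architecture search space.

The searched unit is a *cell*: a small DAG whose nodes are feature maps and
whose edges carry operations drawn from a fixed vocabulary (separable and
dilated separable convolutions, pooling, identity, zero). During search every
edge computes a softmax-weighted mixture of all candidates ("mixed
operation"); the mixture weights are the continuous architecture variables.
After search, the strongest candidate per edge and the two strongest incoming
edges per node are retained, giving a discrete genotype that is stacked into
a deeper network for from-scratch training.

Two cell kinds share architecture variables across their copies: *normal*
cells preserve spatial resolution, *reduction* cells (placed at 1/3 and 2/3
of the stack depth) halve it and double the channel count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import (
    Tensor,
    concat,
    getitem,
    matmul,
    mul,
    relu,
    reshape,
    softmax,
    transpose,
    tsum,
)
from . import nn

# ---------------------------------------------------------------------------
# operation vocabulary
# ---------------------------------------------------------------------------

PRIMITIVES: Tuple[str, ...] = (
    "zero",
    "max_pool_3x3",
    "avg_pool_3x3",
    "skip_connect",
    "sep_conv_3x3",
    "sep_conv_5x5",
    "dil_conv_3x3",
    "dil_conv_5x5",
)


class Zero(nn.Module):
    def __init__(self, stride: int):
        super().__init__()
        self.stride = stride

    def forward(self, x, params=None):
        if self.stride > 1:
            x = getitem(x, (slice(None), slice(None), slice(None, None, self.stride),
                            slice(None, None, self.stride)))
        return mul(x, 0.0)


class Identity(nn.Module):
    def forward(self, x, params=None):
        return x


class Pool(nn.Module):
    def __init__(self, kind: str, stride: int):
        super().__init__()
        self.kind, self.stride = kind, stride

    def forward(self, x, params=None):
        fn = nn.max_pool2d if self.kind == "max" else nn.avg_pool2d
        return fn(x, 3, self.stride, 1)


class ReLUConvBN(nn.Module):
    def __init__(self, c_in, c_out, kernel, stride, padding, rng, dtype, affine=True):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, kernel, stride, padding, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(c_out, affine=affine, dtype=dtype)

    def forward(self, x, params=None):
        return self.bn(self.conv(relu(x), params=params), params=params)


class SepConv(nn.Module):
    """Depthwise-separable convolution applied twice (the standard cell op)."""

    def __init__(self, c, kernel, stride, rng, dtype, affine=True):
        super().__init__()
        pad = kernel // 2
        self.dw1 = nn.Conv2d(c, c, kernel, stride, pad, groups=c, rng=rng, dtype=dtype)
        self.pw1 = nn.Conv2d(c, c, 1, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(c, affine=affine, dtype=dtype)
        self.dw2 = nn.Conv2d(c, c, kernel, 1, pad, groups=c, rng=rng, dtype=dtype)
        self.pw2 = nn.Conv2d(c, c, 1, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(c, affine=affine, dtype=dtype)

    def forward(self, x, params=None):
        x = self.bn1(self.pw1(self.dw1(relu(x), params=params), params=params), params=params)
        x = self.bn2(self.pw2(self.dw2(relu(x), params=params), params=params), params=params)
        return x


class DilConv(nn.Module):
    """Dilated depthwise-separable convolution (dilation 2)."""

    def __init__(self, c, kernel, stride, rng, dtype, affine=True):
        super().__init__()
        pad = kernel - 1  # keeps resolution at stride 1 with dilation 2
        self.dw = nn.Conv2d(c, c, kernel, stride, pad, dilation=2, groups=c, rng=rng, dtype=dtype)
        self.pw = nn.Conv2d(c, c, 1, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(c, affine=affine, dtype=dtype)

    def forward(self, x, params=None):
        return self.bn(self.pw(self.dw(relu(x), params=params), params=params), params=params)


class FactorizedReduce(nn.Module):
    """Stride-2 identity surrogate: two offset 1x1 convolutions, concatenated."""

    def __init__(self, c_in, c_out, rng, dtype, affine=True):
        super().__init__()
        if c_out % 2:
            raise ValueError("FactorizedReduce needs an even channel count")
        self.conv1 = nn.Conv2d(c_in, c_out // 2, 1, stride=2, rng=rng, dtype=dtype)
        self.conv2 = nn.Conv2d(c_in, c_out // 2, 1, stride=2, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(c_out, affine=affine, dtype=dtype)

    def forward(self, x, params=None):
        x = relu(x)
        shifted = getitem(x, (slice(None), slice(None), slice(1, None), slice(1, None)))
        out = concat([self.conv1(x, params=params), self.conv2(shifted, params=params)], axis=1)
        return self.bn(out, params=params)


def _make_op(name: str, c: int, stride: int, rng, dtype, affine: bool) -> nn.Module:
    if name == "zero":
        return Zero(stride)
    if name == "max_pool_3x3":
        return Pool("max", stride)
    if name == "avg_pool_3x3":
        return Pool("avg", stride)
    if name == "skip_connect":
        if stride == 1:
            return Identity()
        return FactorizedReduce(c, c, rng, dtype, affine=affine)
    if name == "sep_conv_3x3":
        return SepConv(c, 3, stride, rng, dtype, affine=affine)
    if name == "sep_conv_5x5":
        return SepConv(c, 5, stride, rng, dtype, affine=affine)
    if name == "dil_conv_3x3":
        return DilConv(c, 3, stride, rng, dtype, affine=affine)
    if name == "dil_conv_5x5":
        return DilConv(c, 5, stride, rng, dtype, affine=affine)
    raise KeyError(f"unknown operation {name!r}")


@dataclass(frozen=True)
class OperationVocabulary:
    """Ordered candidate operations; the index of a name is its mixture slot."""

    names: Tuple[str, ...] = PRIMITIVES

    def __post_init__(self):
        unknown = set(self.names) - set(PRIMITIVES)
        if unknown:
            raise KeyError(f"unknown operations {sorted(unknown)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate operation names")

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def build(self, name: str, c: int, stride: int, rng, dtype, affine: bool) -> nn.Module:
        return _make_op(name, c, stride, rng, dtype, affine)


DEFAULT_VOCAB = OperationVocabulary()


# ---------------------------------------------------------------------------
# architecture containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """Topology of one cell: 2 input nodes + ``num_nodes`` intermediates."""

    num_nodes: int = 4
    reduction: bool = False

    @property
    def num_edges(self) -> int:
        # node i has 2 + i candidate predecessors
        return sum(2 + i for i in range(self.num_nodes))

    def predecessors(self, node: int) -> range:
        return range(2 + node)


@dataclass
class ArchitectureParams:
    """Continuous architecture variables, one real per (edge, operation)."""

    normal: Tensor
    reduce: Tensor

    @staticmethod
    def initialize(num_edges: int, num_ops: int, seed: int = 0,
                   dtype=np.float32, init_std: float = 1e-3) -> "ArchitectureParams":
        rng = np.random.default_rng(seed)
        mk = lambda: Tensor(
            (init_std * rng.standard_normal((num_edges, num_ops))).astype(dtype),
            requires_grad=True,
        )
        return ArchitectureParams(normal=mk(), reduce=mk())

    def tensors(self) -> List[Tensor]:
        return [self.normal, self.reduce]

    @property
    def num_variables(self) -> int:
        return self.normal.size + self.reduce.size


@dataclass
class ExplainerState:
    """All operation weights of the supernet (disjoint from the arch vars)."""

    weights: List[Tensor] = field(default_factory=list)


@dataclass(frozen=True)
class Genotype:
    """Discretized cell: per intermediate node, its two selected input edges."""

    normal: Tuple[Tuple[int, int, str], ...]   # (node, predecessor, op_name)
    reduce: Tuple[Tuple[int, int, str], ...]
    concat: Tuple[int, ...]
    vocab: Tuple[str, ...] = PRIMITIVES

    def to_json(self) -> str:
        return json.dumps(
            {
                "vocab": list(self.vocab),
                "normal": [list(e) for e in self.normal],
                "reduce": [list(e) for e in self.reduce],
                "concat": list(self.concat),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "Genotype":
        d = json.loads(text)
        return Genotype(
            normal=tuple((int(n), int(p), str(o)) for n, p, o in d["normal"]),
            reduce=tuple((int(n), int(p), str(o)) for n, p, o in d["reduce"]),
            concat=tuple(int(i) for i in d["concat"]),
            vocab=tuple(d["vocab"]),
        )

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @staticmethod
    def load(path) -> "Genotype":
        with open(path) as fh:
            return Genotype.from_json(fh.read())


# ---------------------------------------------------------------------------
# mixed operation and supernet
# ---------------------------------------------------------------------------


def mixed_edge_output(x: Tensor, edge_vars: Tensor, ops: Sequence[nn.Module],
                      params=None) -> Tensor:
    """Softmax-weighted sum of all candidate operations on one edge."""
    if edge_vars.size != len(ops):
        raise ValueError(
            f"edge has {len(ops)} candidate ops but {edge_vars.size} variables"
        )
    weights = softmax(reshape(edge_vars, (len(ops),)), axis=0)
    out = None
    ref_shape = None
    for m, op in enumerate(ops):
        y = op(x, params=params)
        if ref_shape is None:
            ref_shape = y.shape
        elif y.shape != ref_shape:
            raise ValueError(
                f"candidate {type(op).__name__} (index {m}) produced shape "
                f"{y.shape}, expected {ref_shape}"
            )
        term = mul(y, getitem(weights, m))
        out = term if out is None else out + term
    return out


class MixedOp(nn.Module):
    def __init__(self, c, stride, vocab: OperationVocabulary, rng, dtype):
        super().__init__()
        self.ops = nn.ModuleList(
            [vocab.build(name, c, stride, rng, dtype, affine=False) for name in vocab.names]
        )

    def forward_mixed(self, x, edge_vars, params=None):
        return mixed_edge_output(x, edge_vars, list(self.ops), params=params)


# -- batched candidate operations ------------------------------------------
#
# All edges entering one node (with equal stride) are evaluated together by
# stacking them along the channel axis: E edges of C channels become one
# E*C-channel tensor, so every candidate operation runs once per node rather
# than once per edge. Depthwise convolutions and batch norm act per channel,
# so stacking is exact; pointwise 1x1 convolutions become a batched matmul
# with one C_out x C_in block per edge. This changes nothing about the
# mixture semantics (see mixed_edge_output) — it is purely an execution
# layout for CPU efficiency.


class BatchedPointwise(nn.Module):
    """Per-edge 1x1 convolution as one batched matmul over E edge blocks."""

    def __init__(self, edges, c_in, c_out, rng, dtype, stride=1):
        super().__init__()
        self.edges, self.c_in, self.c_out, self.stride = edges, c_in, c_out, stride
        std = math.sqrt(2.0 / c_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(edges, 1, c_out, c_in)).astype(dtype),
            requires_grad=True,
        )

    def forward(self, x, params=None):
        w = params.get(id(self.weight), self.weight) if params else self.weight
        n, _, h, wid = x.shape
        if self.stride > 1:
            x = getitem(x, (slice(None), slice(None), slice(None, None, self.stride),
                            slice(None, None, self.stride)))
            h = (h - 1) // self.stride + 1
            wid = (wid - 1) // self.stride + 1
        e, ci, co = self.edges, self.c_in, self.c_out
        x = reshape(x, (n, e, ci, h * wid))
        x = transpose(x, (1, 0, 2, 3))          # [E, N, Ci, HW]
        out = matmul(w, x)                       # [E, N, Co, HW]
        out = transpose(out, (1, 0, 2, 3))
        return reshape(out, (n, e * co, h, wid))


class BatchedSepConv(nn.Module):
    """Depthwise-separable conv applied twice, stacked over E edges."""

    def __init__(self, edges, c, kernel, stride, rng, dtype):
        super().__init__()
        pad = kernel // 2
        ec = edges * c
        self.dw1 = nn.Conv2d(ec, ec, kernel, stride, pad, groups=ec, rng=rng, dtype=dtype)
        self.pw1 = BatchedPointwise(edges, c, c, rng, dtype)
        self.bn1 = nn.BatchNorm2d(ec, affine=False, dtype=dtype)
        self.dw2 = nn.Conv2d(ec, ec, kernel, 1, pad, groups=ec, rng=rng, dtype=dtype)
        self.pw2 = BatchedPointwise(edges, c, c, rng, dtype)
        self.bn2 = nn.BatchNorm2d(ec, affine=False, dtype=dtype)

    def forward(self, x, params=None):
        x = self.bn1(self.pw1(self.dw1(relu(x), params=params), params=params), params=params)
        x = self.bn2(self.pw2(self.dw2(relu(x), params=params), params=params), params=params)
        return x


class BatchedDilConv(nn.Module):
    def __init__(self, edges, c, kernel, stride, rng, dtype):
        super().__init__()
        pad = kernel - 1
        ec = edges * c
        self.dw = nn.Conv2d(ec, ec, kernel, stride, pad, dilation=2, groups=ec,
                            rng=rng, dtype=dtype)
        self.pw = BatchedPointwise(edges, c, c, rng, dtype)
        self.bn = nn.BatchNorm2d(ec, affine=False, dtype=dtype)

    def forward(self, x, params=None):
        return self.bn(self.pw(self.dw(relu(x), params=params), params=params), params=params)


class BatchedFactorizedReduce(nn.Module):
    """Stride-2 identity surrogate per edge block (offset 1x1 convolutions)."""

    def __init__(self, edges, c, rng, dtype):
        super().__init__()
        if c % 2:
            raise ValueError("FactorizedReduce needs an even channel count")
        self.pw1 = BatchedPointwise(edges, c, c // 2, rng, dtype, stride=2)
        self.pw2 = BatchedPointwise(edges, c, c // 2, rng, dtype, stride=2)
        self.bn = nn.BatchNorm2d(edges * c, affine=False, dtype=dtype)
        self.edges, self.c = edges, c

    def forward(self, x, params=None):
        x = relu(x)
        shifted = getitem(x, (slice(None), slice(None), slice(1, None), slice(1, None)))
        a = self.pw1(x, params=params)
        b = self.pw2(shifted, params=params)
        n, _, h, w = a.shape
        half = self.c // 2
        a = reshape(a, (n, self.edges, half, h, w))
        b = reshape(b, (n, self.edges, half, h, w))
        out = concat([a, b], axis=2)
        return self.bn(reshape(out, (n, self.edges * self.c, h, w)), params=params)


class EdgeGroup(nn.Module):
    """All candidate operations for E same-stride edges entering one node."""

    def __init__(self, edges, c, stride, vocab: OperationVocabulary, rng, dtype):
        super().__init__()
        self.edges, self.c, self.stride = edges, c, stride
        self.names = vocab.names
        ops = []
        ec = edges * c
        for name in vocab.names:
            if name == "zero":
                ops.append(Zero(stride))
            elif name == "max_pool_3x3":
                ops.append(Pool("max", stride))
            elif name == "avg_pool_3x3":
                ops.append(Pool("avg", stride))
            elif name == "skip_connect":
                ops.append(Identity() if stride == 1
                           else BatchedFactorizedReduce(edges, c, rng, dtype))
            elif name == "sep_conv_3x3":
                ops.append(BatchedSepConv(edges, c, 3, stride, rng, dtype))
            elif name == "sep_conv_5x5":
                ops.append(BatchedSepConv(edges, c, 5, stride, rng, dtype))
            elif name == "dil_conv_3x3":
                ops.append(BatchedDilConv(edges, c, 3, stride, rng, dtype))
            elif name == "dil_conv_5x5":
                ops.append(BatchedDilConv(edges, c, 5, stride, rng, dtype))
            else:  # pragma: no cover - vocabulary is validated upstream
                raise KeyError(name)
        self.ops = nn.ModuleList(ops)

    def forward_mixed(self, inputs, weights, params=None):
        """inputs: list of E state tensors; weights: [E, M] softmax rows.

        Returns the per-edge mixed outputs summed over the group's edges
        (the contribution of these edges to their node).
        """
        x = concat(inputs, axis=1) if len(inputs) > 1 else inputs[0]
        n = x.shape[0]
        acc = None
        for m, op in enumerate(self.ops):
            y = op(x, params=params)
            h, w = y.shape[2], y.shape[3]
            y = reshape(y, (n, self.edges, self.c, h, w))
            wm = reshape(getitem(weights, (slice(None), m)), (1, self.edges, 1, 1, 1))
            term = mul(y, wm)
            acc = term if acc is None else acc + term
        return tsum(acc, axis=1)


class SearchCell(nn.Module):
    def __init__(self, spec: CellSpec, c_pp, c_p, c, reduction_prev,
                 vocab, rng, dtype):
        super().__init__()
        self.spec = spec
        if reduction_prev:
            self.pre0 = FactorizedReduce(c_pp, c, rng, dtype, affine=False)
        else:
            self.pre0 = ReLUConvBN(c_pp, c, 1, 1, 0, rng, dtype, affine=False)
        self.pre1 = ReLUConvBN(c_p, c, 1, 1, 0, rng, dtype, affine=False)
        # per node, one EdgeGroup per stride class (reduction cells stride-2
        # the two cell inputs only)
        groups = []
        self.plan = []  # (node, [predecessors], group_index, [edge_offsets])
        offset = 0
        for i in range(spec.num_nodes):
            preds = list(spec.predecessors(i))
            if spec.reduction:
                classes = [(2, [j for j in preds if j < 2]),
                           (1, [j for j in preds if j >= 2])]
            else:
                classes = [(1, preds)]
            for stride, js in classes:
                if not js:
                    continue
                groups.append(EdgeGroup(len(js), c, stride, vocab, rng, dtype))
                self.plan.append((i, js, len(groups) - 1,
                                  [offset + j for j in js]))
            offset += len(preds)
        self.groups = nn.ModuleList(groups)

    def forward_cell(self, s0, s1, arch_matrix: Tensor, params=None):
        soft = softmax(arch_matrix, axis=1)
        states = [self.pre0(s0, params=params), self.pre1(s1, params=params)]
        for i in range(self.spec.num_nodes):
            acc = None
            for node, js, gidx, rows in self.plan:
                if node != i:
                    continue
                if len(rows) == rows[-1] - rows[0] + 1:
                    w = getitem(soft, slice(rows[0], rows[-1] + 1))
                else:
                    w = concat([getitem(soft, slice(r, r + 1)) for r in rows], axis=0)
                term = self.groups[gidx].forward_mixed(
                    [states[j] for j in js], w, params=params
                )
                acc = term if acc is None else acc + term
            states.append(acc)
        return concat(states[2:], axis=1)


class SuperNet(nn.Module):
    """Stack of search cells with shared architecture variables."""

    def __init__(self, cells: int, num_nodes: int, init_channels: int,
                 num_classes: int, in_channels: int, vocab, rng, dtype,
                 stem_multiplier: int = 3):
        super().__init__()
        self.vocab = vocab
        self.num_nodes = num_nodes
        c_curr = stem_multiplier * init_channels
        self.stem_conv = nn.Conv2d(in_channels, c_curr, 3, 1, 1, rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(c_curr, dtype=dtype)
        self.reduction_positions = reduction_positions(cells)
        c_pp, c_p, c = c_curr, c_curr, init_channels
        cell_list = []
        reduction_prev = False
        for idx in range(cells):
            reduction = idx in self.reduction_positions
            if reduction:
                c *= 2
            spec = CellSpec(num_nodes=num_nodes, reduction=reduction)
            cell = SearchCell(spec, c_pp, c_p, c, reduction_prev, vocab, rng, dtype)
            cell_list.append(cell)
            reduction_prev = reduction
            c_pp, c_p = c_p, c * num_nodes
        self.cells = nn.ModuleList(cell_list)
        self.classifier = nn.Linear(c_p, num_classes, rng=rng, dtype=dtype)
        self.arch: Optional[ArchitectureParams] = None  # attached by build_supernet

    def forward(self, x, params=None, arch: Optional[ArchitectureParams] = None):
        arch = arch if arch is not None else self.arch
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        s0 = s1 = self.stem_bn(self.stem_conv(x, params=params), params=params)
        for cell in self.cells:
            mat = arch.reduce if cell.spec.reduction else arch.normal
            s0, s1 = s1, cell.forward_cell(s0, s1, mat, params=params)
        return self.classifier(nn.global_avg_pool(s1), params=params)


def reduction_positions(cells: int) -> Tuple[int, ...]:
    return tuple(sorted({cells // 3, (2 * cells) // 3} & set(range(cells))))


def build_supernet(cells: int, num_nodes: int = 4, init_channels: int = 16,
                   num_classes: int = 4, in_channels: int = 1,
                   vocab: OperationVocabulary = DEFAULT_VOCAB,
                   stem_multiplier: int = 3, seed: int = 0,
                   dtype=np.float32,
                   ) -> Tuple[SuperNet, ArchitectureParams, ExplainerState]:
    """Construct the over-parameterized search network.

    Returns the network, its architecture variables (one [num_edges x M]
    matrix per cell kind, shared across cells of that kind), and the
    collection of operation weights.
    """
    if cells < 2:
        raise ValueError("a supernet needs at least 2 cells")
    if init_channels <= 0:
        raise ValueError("init_channels must be positive")
    rng = np.random.default_rng(seed)
    net = SuperNet(cells, num_nodes, init_channels, num_classes, in_channels,
                   vocab, rng, dtype, stem_multiplier)
    spec = CellSpec(num_nodes=num_nodes)
    arch = ArchitectureParams.initialize(spec.num_edges, len(vocab), seed=seed + 1,
                                         dtype=dtype)
    net.arch = arch
    return net, arch, ExplainerState(weights=net.parameters())


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def _softmax_np(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def derive_genotype(arch: ArchitectureParams, vocab: OperationVocabulary = DEFAULT_VOCAB,
                    num_nodes: Optional[int] = None, top_k: int = 2) -> Genotype:
    """Keep, per edge, its strongest non-zero operation and, per node, the
    ``top_k`` strongest incoming edges; ties break toward the lowest index."""

    def pick(matrix: np.ndarray) -> Tuple[Tuple[int, int, str], ...]:
        if not np.all(np.isfinite(matrix)):
            raise ValueError("architecture variables must be finite")
        w = _softmax_np(np.asarray(matrix, dtype=np.float64))
        nodes = _infer_nodes(w.shape[0]) if num_nodes is None else num_nodes
        spec = CellSpec(num_nodes=nodes)
        selected = []
        offset = 0
        for i in range(nodes):
            cand = []
            for j in spec.predecessors(i):
                row = w[offset + j].copy()
                zero_idx = vocab.names.index("zero") if "zero" in vocab.names else None
                if zero_idx is not None:
                    row[zero_idx] = -np.inf
                best_op = int(np.argmax(row))  # first occurrence on ties
                cand.append((-row[best_op], j, best_op))
            cand.sort()  # by descending weight, then lowest predecessor
            k = min(top_k, len(cand))
            for _, j, op in sorted(cand[:k], key=lambda t: t[1]):
                selected.append((i, j, vocab.names[op]))
            offset += len(spec.predecessors(i))
        return tuple(selected)

    nodes = _infer_nodes(arch.normal.shape[0]) if num_nodes is None else num_nodes
    return Genotype(
        normal=pick(arch.normal.data),
        reduce=pick(arch.reduce.data),
        concat=tuple(range(2, 2 + nodes)),
        vocab=vocab.names,
    )


def _infer_nodes(num_edges: int) -> int:
    n = 0
    total = 0
    while total < num_edges:
        total += 2 + n
        n += 1
    if total != num_edges:
        raise ValueError(f"edge count {num_edges} does not match any node count")
    return n


# ---------------------------------------------------------------------------
# discrete evaluation network
# ---------------------------------------------------------------------------


class EvalCell(nn.Module):
    def __init__(self, genotype: Genotype, c_pp, c_p, c, reduction, reduction_prev,
                 rng, dtype):
        super().__init__()
        self.reduction = reduction
        self.concat = genotype.concat
        if reduction_prev:
            self.pre0 = FactorizedReduce(c_pp, c, rng, dtype)
        else:
            self.pre0 = ReLUConvBN(c_pp, c, 1, 1, 0, rng, dtype)
        self.pre1 = ReLUConvBN(c_p, c, 1, 1, 0, rng, dtype)
        edges = genotype.reduce if reduction else genotype.normal
        self.edges = tuple((int(n), int(p)) for n, p, _ in edges)
        vocab = OperationVocabulary(genotype.vocab)
        ops = []
        for node, pred, op_name in edges:
            if op_name not in vocab.names:
                raise KeyError(f"operation {op_name!r} not in vocabulary")
            stride = 2 if reduction and pred < 2 else 1
            ops.append(_make_op(op_name, c, stride, rng, dtype, affine=True))
        self.ops = nn.ModuleList(ops)
        self.num_nodes = 1 + max(n for n, _ in self.edges)

    def forward_cell(self, s0, s1, params=None):
        states = [self.pre0(s0, params=params), self.pre1(s1, params=params)]
        per_node: Dict[int, List[int]] = {}
        for k, (node, _) in enumerate(self.edges):
            per_node.setdefault(node, []).append(k)
        for i in range(self.num_nodes):
            acc = None
            for k in per_node.get(i, []):
                _, pred = self.edges[k]
                term = self.ops[k](states[pred], params=params)
                acc = term if acc is None else acc + term
            states.append(acc)
        return concat([states[i] for i in self.concat], axis=1)


class EvalNetwork(nn.Module):
    """Discrete network: stacked copies of the derived cell."""

    def __init__(self, genotype: Genotype, layers: int, init_channels: int,
                 num_classes: int, in_channels: int, rng, dtype,
                 stem_multiplier: int = 3):
        super().__init__()
        c_curr = stem_multiplier * init_channels
        self.stem_conv = nn.Conv2d(in_channels, c_curr, 3, 1, 1, rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(c_curr, dtype=dtype)
        positions = reduction_positions(layers)
        mult = len(genotype.concat)
        c_pp, c_p, c = c_curr, c_curr, init_channels
        cell_list = []
        reduction_prev = False
        for idx in range(layers):
            reduction = idx in positions
            if reduction:
                c *= 2
            cell = EvalCell(genotype, c_pp, c_p, c, reduction, reduction_prev, rng, dtype)
            cell_list.append(cell)
            reduction_prev = reduction
            c_pp, c_p = c_p, c * mult
        self.cells = nn.ModuleList(cell_list)
        self.classifier = nn.Linear(c_p, num_classes, rng=rng, dtype=dtype)

    def forward(self, x, params=None):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        s0 = s1 = self.stem_bn(self.stem_conv(x, params=params), params=params)
        for cell in self.cells:
            s0, s1 = s1, cell.forward_cell(s0, s1, params=params)
        return self.classifier(nn.global_avg_pool(s1), params=params)


def build_eval_network(genotype: Genotype, layers: int = 12, init_channels: int = 36,
                       num_classes: int = 4, in_channels: int = 1, seed: int = 0,
                       dtype=np.float32) -> EvalNetwork:
    """Build the discrete network used for from-scratch retraining."""
    rng = np.random.default_rng(seed)
    return EvalNetwork(genotype, layers, init_channels, num_classes, in_channels,
                       rng, dtype)


def count_parameters(network: nn.Module) -> int:
    """Exact number of trainable scalars in the network."""
    return int(sum(p.size for p in network.parameters()))
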