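"""Audience models: fixed, human-designed networks trained on explanations.

The audience has no architecture variables; only its weights W are
trainable, and during search they move exclusively through the one-step
update on explanation-reweighted images. Its validation loss measures how
useful the explainer's explanations are as a training signal, which is the
feedback the architecture update consumes.

Supported architectures: ``resnet18`` (small-image variant: 3x3 stem,
stride 1, no initial max-pool), ``vgg13``, and ``small_cnn`` (a 4-layer
network for desk-scale experiments and tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

from .autograd import Tensor, grad, relu
from . import nn
from .explanations import LabeledBatch

__all__ = [
    "AudienceState",
    "build_audience",
    "audience_unrolled_step",
    "audience_validation_loss",
    "save_audience_checkpoint",
    "load_audience_checkpoint",
    "SUPPORTED_AUDIENCES",
]

SUPPORTED_AUDIENCES = ("resnet18", "vgg13", "small_cnn")


@dataclass
class AudienceState:
    architecture_name: str
    weights: List[Tensor] = field(default_factory=list)


class BasicBlock(nn.Module):
    def __init__(self, c_in, c_out, stride, rng, dtype):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(c_out, dtype=dtype)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(c_out, dtype=dtype)
        self.downsample = None
        if stride != 1 or c_in != c_out:
            self.downsample = nn.Sequential(
                nn.Conv2d(c_in, c_out, 1, stride, 0, rng=rng, dtype=dtype),
                nn.BatchNorm2d(c_out, dtype=dtype),
            )

    def forward(self, x, params=None):
        out = relu(self.bn1(self.conv1(x, params=params), params=params))
        out = self.bn2(self.conv2(out, params=params), params=params)
        shortcut = x if self.downsample is None else self.downsample(x, params=params)
        return relu(out + shortcut)


class ResNet18(nn.Module):
    """ResNet-18 with a small-image stem (3x3, stride 1, no max-pool)."""

    def __init__(self, num_classes, in_channels, rng, dtype, width=64):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(in_channels, width, 3, 1, 1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(width, dtype=dtype),
            nn.ReLU(),
        )
        blocks = []
        c_in = width
        for stage, (c_out, stride) in enumerate(
            [(width, 1), (2 * width, 2), (4 * width, 2), (8 * width, 2)]
        ):
            blocks.append(BasicBlock(c_in, c_out, stride, rng, dtype))
            blocks.append(BasicBlock(c_out, c_out, 1, rng, dtype))
            c_in = c_out
        self.blocks = nn.ModuleList(blocks)
        self.fc = nn.Linear(c_in, num_classes, rng=rng, dtype=dtype)

    def forward(self, x, params=None):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        h = self.stem(x, params=params)
        for b in self.blocks:
            h = b(h, params=params)
        return self.fc(nn.global_avg_pool(h), params=params)


class VGG13(nn.Module):
    def __init__(self, num_classes, in_channels, rng, dtype):
        super().__init__()
        cfg = [64, 64, "M", 128, 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"]
        layers = []
        c_in = in_channels
        for item in cfg:
            if item == "M":
                layers.append(("pool", None))
            else:
                layers.append(("conv", nn.Conv2d(c_in, item, 3, 1, 1, rng=rng, dtype=dtype)))
                layers.append(("bn", nn.BatchNorm2d(item, dtype=dtype)))
                c_in = item
        self.ops = nn.ModuleList([m for kind, m in layers if m is not None])
        self._plan = [kind for kind, _ in layers]
        self.fc = nn.Linear(c_in, num_classes, rng=rng, dtype=dtype)

    def forward(self, x, params=None):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        h = x
        it = iter(self.ops)
        for kind in self._plan:
            if kind == "pool":
                h = nn.max_pool2d(h, 2, 2, 0)
            elif kind == "conv":
                h = next(it)(h, params=params)
            else:  # bn + relu
                h = relu(next(it)(h, params=params))
        return self.fc(nn.global_avg_pool(h), params=params)


class SmallCNN(nn.Module):
    """4-layer CNN: two conv+BN+pool stages and two fully-connected layers."""

    def __init__(self, num_classes, in_channels, rng, dtype, width=8):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, width, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(width, dtype=dtype)
        self.conv2 = nn.Conv2d(width, 2 * width, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(2 * width, dtype=dtype)
        self.fc1 = nn.Linear(2 * width, 4 * width, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(4 * width, num_classes, rng=rng, dtype=dtype)

    def forward(self, x, params=None):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        h = relu(self.bn1(self.conv1(x, params=params), params=params))
        h = nn.max_pool2d(h, 2, 2, 0)
        h = relu(self.bn2(self.conv2(h, params=params), params=params))
        h = nn.global_avg_pool(h)
        h = relu(self.fc1(h, params=params))
        return self.fc2(h, params=params)


def build_audience(name: str, num_classes: int = 4, input_size: int = 64,
                   in_channels: int = 1, seed: int = 0, dtype=np.float32):
    """Instantiate an audience network with freshly seeded weights.

    Returns ``(state, network)``; ``input_size`` is recorded for sanity only
    (all audiences are fully convolutional up to the head).
    """
    if name not in SUPPORTED_AUDIENCES:
        raise KeyError(
            f"unknown audience {name!r}; supported: {', '.join(SUPPORTED_AUDIENCES)}"
        )
    rng = np.random.default_rng(seed)
    if name == "resnet18":
        net = ResNet18(num_classes, in_channels, rng, dtype)
    elif name == "vgg13":
        net = VGG13(num_classes, in_channels, rng, dtype)
    else:
        net = SmallCNN(num_classes, in_channels, rng, dtype)
    return AudienceState(architecture_name=name, weights=net.parameters()), net


def save_audience_checkpoint(path, state: AudienceState, net: nn.Module) -> None:
    """Serialize audience weights (and BN statistics) with the architecture
    name embedded for validation on load."""
    arrays = net.state_arrays()
    np.savez(path, __architecture__=np.array(state.architecture_name), **arrays)


def load_audience_checkpoint(path, net: nn.Module,
                             expected_architecture: Optional[str] = None) -> str:
    """Restore a checkpoint written by :func:`save_audience_checkpoint`.

    Raises if the stored architecture name does not match ``expected``.
    """
    with np.load(path, allow_pickle=False) as data:
        name = str(data["__architecture__"])
        if expected_architecture is not None and name != expected_architecture:
            raise ValueError(
                f"checkpoint holds a {name!r} audience, expected "
                f"{expected_architecture!r}"
            )
        net.load_state_arrays({k: data[k] for k in data.files
                               if k != "__architecture__"})
    return name


def audience_unrolled_step(net: nn.Module, weighted_images: Tensor,
                           labels: np.ndarray, xi_w: float,
                           params: Optional[Mapping[int, Tensor]] = None,
                           create_graph: bool = False) -> Dict[int, Tensor]:
    """One plain gradient-descent step of the audience on reweighted images.

    Returns a functional override mapping ``id(W_i) -> W'_i`` with
    ``W' = W - xi_w * grad`` from a single step on the mean cross-entropy.
    The step excludes momentum and weight decay so that its derivative with
    respect to the reweighted images is the literal second-derivative term
    the architecture gradient needs.
    """
    if xi_w < 0:
        raise ValueError("xi_w must be nonnegative")
    weights = net.parameters()
    logits = net(weighted_images, params=params)
    loss = nn.cross_entropy(logits, labels)
    if not np.isfinite(loss.item()):
        raise FloatingPointError("non-finite audience training loss")
    base = [(params or {}).get(id(p), p) for p in weights]
    gs = grad(loss, base, create_graph=create_graph)
    out: Dict[int, Tensor] = {}
    for p, b, g in zip(weights, base, gs):
        out[id(p)] = b if g is None or xi_w == 0 else b - xi_w * g
    return out


def audience_validation_loss(net: nn.Module, val_batch: LabeledBatch,
                             params: Optional[Mapping[int, Tensor]] = None) -> Tensor:
    """Mean cross-entropy of the audience on raw validation images."""
    logits = net(Tensor(val_batch.images), params=params)
    return nn.cross_entropy(logits, val_batch.labels)
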