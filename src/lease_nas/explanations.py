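"""Adversarial-perturbation explanations and pixel reweighting.

The explainer "explains" a prediction by finding, for each image, the
perturbation delta (bounded in L-infinity norm by ``tau``) that most changes
its own predictive distribution: pixels that admit large effective
perturbations are deemed decision-relevant. The perturbations then reweigh
the pixels of the audience's training images, ``x * delta``, so that the
audience learns predominantly from regions the explainer considers
important.

The perturbation search is a single (by default) projected gradient step on
the divergence between the perturbed and clean predictive distributions.
Run with ``create_graph=True`` the step stays differentiable with respect to
the explainer weights, which the search engine requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autograd import Tensor, clip, div, grad, log, mul, relu, tmax, tsum, reshape, softmax
from . import nn

__all__ = [
    "LabeledBatch",
    "PerturbationBatch",
    "attack_divergence",
    "generate_explanations",
    "reweight_images",
    "save_explanation_heatmaps",
]


@dataclass
class LabeledBatch:
    """Images in [0, 1], NCHW, with integer class labels."""

    images: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError("images must be [N, C, H, W]")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("labels and images disagree on N")
        if len(self.labels) < 1:
            raise ValueError("batch must contain at least one example")

    def __len__(self):
        return self.images.shape[0]


@dataclass
class PerturbationBatch:
    """Per-image perturbations with the same shape as their batch."""

    deltas: Tensor
    tau: float

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    def check_feasible(self, atol: float = 1e-7) -> bool:
        return bool(np.abs(self.deltas.data).max() <= self.tau + atol)


def attack_divergence(p_perturbed, p_original, eps: float = 1e-12) -> Tensor:
    """Cross-entropy -sum(b * log a) between two predictive distributions.

    ``a`` is the distribution on the perturbed image, ``b`` on the original.
    A probability floor ``eps`` inside the logarithm guards saturated
    softmax outputs.
    """
    a = p_perturbed if isinstance(p_perturbed, Tensor) else Tensor(np.asarray(p_perturbed))
    b = p_original if isinstance(p_original, Tensor) else Tensor(np.asarray(p_original))
    if a.shape != b.shape:
        raise ValueError(f"probability vectors disagree in shape: {a.shape} vs {b.shape}")
    return -tsum(mul(b, log(clip(a, eps, 1.0))), axis=-1).mean()


def _divergence_from_logits(z_perturbed: Tensor, z_original: Tensor) -> Tensor:
    """Numerically stable divergence computed from raw logits."""
    from .autograd import log_softmax

    b = softmax(z_original, axis=-1)
    return (-tsum(mul(b, log_softmax(z_perturbed, axis=-1)), axis=-1)).mean()


def generate_explanations(model: nn.Module, batch: LabeledBatch, tau: float,
                          xi_delta: float, steps: int = 1,
                          params=None, init: str = "uniform",
                          attack_sign: str = "ascent",
                          rng: Optional[np.random.Generator] = None,
                          create_graph: bool = False) -> PerturbationBatch:
    """Projected-gradient perturbations maximizing the prediction divergence.

    Parameters
    ----------
    model : network mapping images to K logits.
    params : optional functional weight override (e.g. unrolled weights E').
    attack_sign : ``"ascent"`` moves delta up the divergence gradient (the
        maximization the explanation objective states); ``"descent"`` applies
        the opposite sign for comparison.
    create_graph : keep the step differentiable w.r.t. the model weights.

    Notes
    -----
    The default initialization draws delta uniformly from the feasible ball
    ("adds small random perturbations"). A zero initialization is available
    but degenerate for a one-step attack: the divergence is minimized at
    delta = 0, so its gradient there vanishes identically and the step
    returns the initialization unchanged.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if attack_sign not in ("ascent", "descent"):
        raise ValueError("attack_sign must be 'ascent' or 'descent'")
    sign = 1.0 if attack_sign == "ascent" else -1.0
    dtype = batch.images.dtype
    if init == "zeros":
        delta = Tensor(np.zeros_like(batch.images))
    elif init == "uniform":
        rng = rng or np.random.default_rng(0)
        delta = Tensor(rng.uniform(-tau, tau, size=batch.images.shape).astype(dtype))
    else:
        raise ValueError("init must be 'zeros' or 'uniform'")

    x = Tensor(batch.images)
    for _ in range(steps):
        d = Tensor(delta.data, requires_grad=True) if not create_graph else delta
        if create_graph and not d.requires_grad:
            d = Tensor(d.data, requires_grad=True)
        z_orig = model(x, params=params)
        z_pert = model(x + d, params=params)
        obj = _divergence_from_logits(z_pert, z_orig)
        (g,) = grad(obj, [d], create_graph=create_graph)
        if g is None:
            g = Tensor(np.zeros_like(d.data))
        if not np.all(np.isfinite(g.data)):
            bad = np.argwhere(~np.isfinite(g.data.reshape(len(batch), -1)).all(axis=1))
            raise FloatingPointError(
                f"non-finite attack gradient for batch index {int(bad[0])}"
            )
        delta = clip(d + sign * xi_delta * g, -tau, tau)
    return PerturbationBatch(deltas=delta, tau=tau)


def reweight_images(batch: LabeledBatch, perturbations: PerturbationBatch,
                    mode: str = "raw") -> Tensor:
    """Pixel reweighting ``x * delta`` consumed by the audience.

    ``mode="raw"`` multiplies by the signed perturbation exactly as the
    training objective of the audience states. ``mode="abs_norm"`` instead
    uses ``|delta|`` rescaled to [0, 1] per image, a variant that preserves
    image polarity and overall intensity scale.
    """
    delta = perturbations.deltas
    if delta.shape != batch.images.shape:
        raise ValueError(
            f"perturbation shape {delta.shape} does not match images "
            f"{batch.images.shape}"
        )
    x = Tensor(batch.images)
    if mode == "raw":
        return mul(x, delta)
    if mode == "abs_norm":
        mag = relu(delta) + relu(-delta)
        n = delta.shape[0]
        peak = tmax(reshape(mag, (n, -1)), axis=1)
        peak = clip(peak, 1e-12, np.inf)
        scale = reshape(div(1.0, peak), (n, 1, 1, 1))
        return mul(x, mul(mag, scale))
    raise ValueError("mode must be 'raw' or 'abs_norm'")


def save_explanation_heatmaps(perturbations: PerturbationBatch, path) -> None:
    """Write one grayscale PNG heatmap of |delta| per image (for inspection)."""
    from pathlib import Path

    from PIL import Image

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    deltas = perturbations.deltas.data
    for i, d in enumerate(deltas):
        mag = np.abs(d).mean(axis=0)  # average over channels
        peak = mag.max()
        if peak > 0:
            mag = mag / peak
        arr = np.round(mag * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / f"explanation_{i:04d}.png")
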