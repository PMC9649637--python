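"""Four-level self-explanation architecture search.

One search step runs four stages on four minibatches (explainer train/val,
audience train/val):

1. a one-step gradient update of the explainer weights, E' = E - xi_e * dE;
2. a one-step projected attack producing per-image explanations delta';
3. a one-step update of the audience weights W' on delta'-reweighted images;
4. an architecture update descending d/dA [ L(E', val_e) + gamma * L(W', val_a) ].

Because stages 1-3 are single explicit gradient steps, the stage-4 gradient
is a hypergradient through them. Two evaluation paths are provided:

* ``hypergrad="exact"`` — reverse-mode differentiation through the unrolled
  graph (the default; exact for the objective as implemented, including the
  direct dependence of every stage on A);
* ``hypergrad="fd"`` — the chain of symmetric finite-difference
  contractions with step alpha = alpha_scale / ||v||_2, which approximates
  each second-derivative factor by two extra gradient evaluations and never
  materializes a Hessian. With ``objective_mode="explainer_only"`` this path
  reproduces the classic second-order differentiable-NAS update exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor, grad, no_grad
from . import nn
from .audience import audience_unrolled_step, audience_validation_loss
from .explanations import (
    LabeledBatch,
    PerturbationBatch,
    generate_explanations,
    reweight_images,
)
from .search_space import (
    ArchitectureParams,
    Genotype,
    OperationVocabulary,
    SuperNet,
    derive_genotype,
)

__all__ = [
    "LeaseConfig",
    "SearchState",
    "DataSplits",
    "explainer_unroll",
    "fd_matvec",
    "arch_grad_explainer_term",
    "arch_grad_audience_term",
    "lease_search_step",
    "run_search",
]


@dataclass
class LeaseConfig:
    """Scalars of the search objective and its optimizers.

    Unroll step sizes ``xi_e``/``xi_w`` default (``None``) to the current
    learning rate of the corresponding real optimizer, the usual convention
    for one-step approximations.
    """

    gamma: float = 1.0                     # audience-loss tradeoff
    tau: float = 0.1                       # L-inf radius of explanations
    xi_e: Optional[float] = None           # explainer unroll step
    xi_delta: float = 1.0                  # attack step
    xi_w: Optional[float] = None           # audience unroll step
    eta: float = 3e-4                      # architecture (Adam) learning rate
    alpha_scale: float = 0.01              # numerator of the FD probe step
    objective_mode: str = "combined"       # combined | audience_only | explainer_only
    attack_sign: str = "ascent"            # ascent | descent
    attack_init: str = "uniform"           # uniform | zeros (zeros is degenerate
                                           # for a one-step attack: zero gradient)
    attack_steps: int = 1
    reweight_mode: str = "raw"             # raw | abs_norm
    hypergrad: str = "exact"               # exact | fd
    epochs: int = 50
    batch_size: int = 64
    steps_per_epoch: Optional[int] = None  # cap on search steps per epoch
                                           # (None = one step per minibatch)
    eval_subset: Optional[int] = None      # images used for the per-epoch
                                           # search-validation metrics
    lr: float = 0.025                      # weight SGD initial learning rate
    lr_min: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 3e-4
    arch_weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("xi_delta", "eta", "lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.objective_mode not in ("combined", "audience_only", "explainer_only"):
            raise ValueError(f"unknown objective_mode {self.objective_mode!r}")
        if self.hypergrad not in ("exact", "fd"):
            raise ValueError(f"unknown hypergrad {self.hypergrad!r}")


@dataclass
class DataSplits:
    """The two halves of the training pool.

    Part 1 serves as training data for both explainer and audience; part 2
    serves as both validation sets.
    """

    part1: LabeledBatch
    part2: LabeledBatch


@dataclass
class SearchState:
    explainer: object
    audience: object
    arch: ArchitectureParams
    epoch: int = 0
    step: int = 0
    history: List[dict] = field(default_factory=list)
    history_epochs: List[dict] = field(default_factory=list)

    def save(self, path) -> None:
        """Serialize weights, architecture variables and counters for resume
        (history goes to the search log, not the checkpoint)."""
        arrays = {f"explainer.{k}": v for k, v in self.explainer.state_arrays().items()}
        arrays.update({f"audience.{k}": v for k, v in self.audience.state_arrays().items()})
        np.savez(path, __normal__=self.arch.normal.data,
                 __reduce__=self.arch.reduce.data,
                 __counters__=np.array([self.epoch, self.step]), **arrays)

    def load(self, path) -> "SearchState":
        with np.load(path, allow_pickle=False) as data:
            self.arch.normal.data = data["__normal__"].copy()
            self.arch.reduce.data = data["__reduce__"].copy()
            self.epoch, self.step = (int(v) for v in data["__counters__"])
            self.explainer.load_state_arrays(
                {k[len("explainer."):]: data[k] for k in data.files
                 if k.startswith("explainer.")})
            self.audience.load_state_arrays(
                {k[len("audience."):]: data[k] for k in data.files
                 if k.startswith("audience.")})
        return self


# ---------------------------------------------------------------------------
# unrolled one-step maps and hypergradient terms
# ---------------------------------------------------------------------------


def explainer_unroll(net, batch: LabeledBatch, xi_e: float,
                     create_graph: bool = False,
                     arch: Optional[ArchitectureParams] = None):
    """E' = E - xi_e * dL/dE on the explainer's training cross-entropy.

    Returns ``(override dict id(E_i)->E'_i, loss, grads)``. With
    ``create_graph`` the E' tensors stay differentiable w.r.t. the
    architecture variables.
    """
    if xi_e < 0:
        raise ValueError("xi_e must be nonnegative")
    weights = net.parameters()
    kwargs = {"arch": arch} if arch is not None else {}
    loss = nn.cross_entropy(net(Tensor(batch.images), **kwargs), batch.labels)
    if not np.isfinite(loss.item()):
        raise FloatingPointError("non-finite explainer training loss")
    gs = grad(loss, weights, create_graph=create_graph)
    out = {}
    for p, g in zip(weights, gs):
        out[id(p)] = p if (g is None or xi_e == 0) else p - xi_e * g
    return out, loss, gs


def _flat_norm(vs: Sequence[Optional[Tensor]]) -> float:
    total = 0.0
    for v in vs:
        if v is not None:
            total += float(np.sum(v.data.astype(np.float64) ** 2))
    return math.sqrt(total)


def fd_matvec(train_loss_fn: Callable[[], Tensor], A: Sequence[Tensor],
              E: Sequence[Tensor], v: Sequence[Optional[Tensor]],
              alpha_scale: float = 0.01) -> List[Tensor]:
    """Symmetric-difference approximation of the mixed second derivative
    contraction  d2L/dA dE . v  using two gradient evaluations at E +- a*v,
    with a = alpha_scale / ||v||_2 (exact for objectives quadratic in E).
    """
    norm = _flat_norm(v)
    if norm == 0.0:
        return [Tensor(np.zeros_like(a.data)) for a in A]
    alpha = alpha_scale / norm

    def grads_at(sign: float) -> List[np.ndarray]:
        for p, vi in zip(E, v):
            if vi is not None:
                p.data = p.data + sign * alpha * vi.data.astype(p.dtype)
        try:
            gs = grad(train_loss_fn(), list(A))
        finally:
            for p, vi in zip(E, v):
                if vi is not None:
                    p.data = p.data - sign * alpha * vi.data.astype(p.dtype)
        return [np.zeros_like(a.data) if g is None else g.data for g, a in zip(gs, A)]

    gp = grads_at(+1.0)
    gm = grads_at(-1.0)
    return [Tensor((p - m) / (2 * alpha)) for p, m in zip(gp, gm)]


def arch_grad_explainer_term(train_loss_fn: Callable[[Optional[dict]], Tensor],
                             val_loss_fn: Callable[[Optional[dict]], Tensor],
                             E: Sequence[Tensor], A: Sequence[Tensor],
                             xi_e: float, alpha_scale: float = 0.01,
                             mode: str = "fd") -> List[Tensor]:
    """Hypergradient of the explainer's validation loss w.r.t. A through the
    one-step update E' = E - xi_e * dL_tr/dE.

    ``train_loss_fn(params)`` / ``val_loss_fn(params)`` evaluate the two
    losses, optionally at overridden weights. ``mode="exact"`` differentiates
    through the unrolled graph; ``mode="fd"`` uses the two-term expansion
    dL_val/dA  -  xi_e * d2L_tr/dAdE . dL_val/dE'  with the mixed second
    derivative approximated by :func:`fd_matvec`.
    """
    E, A = list(E), list(A)
    if mode == "exact":
        gs = grad(train_loss_fn(None), E, create_graph=True)
        override = {
            id(p): (p if (g is None or xi_e == 0) else p - xi_e * g)
            for p, g in zip(E, gs)
        }
        val = val_loss_fn(override)
        out = grad(val, A)
        return [Tensor(np.zeros_like(a.data)) if g is None else g for g, a in zip(out, A)]
    if mode != "fd":
        raise ValueError("mode must be 'exact' or 'fd'")
    gs = grad(train_loss_fn(None), E)
    e_prime = [Tensor(p.data if (g is None or xi_e == 0) else p.data - xi_e * g.data,
                      requires_grad=True)
               for p, g in zip(E, gs)]
    override = {id(p): ep for p, ep in zip(E, e_prime)}
    val = val_loss_fn(override)
    all_grads = grad(val, e_prime + A)
    v, direct = all_grads[: len(E)], all_grads[len(E):]
    direct = [Tensor(np.zeros_like(a.data)) if g is None else g for g, a in zip(direct, A)]
    if xi_e == 0:
        return direct
    hv = fd_matvec(lambda: train_loss_fn(None), A, E, v, alpha_scale)
    return [Tensor(d.data - xi_e * h.data) for d, h in zip(direct, hv)]


def _probe_second_derivative(loss_fn: Callable[[], Tensor],
                             wrt: Sequence[Tensor],
                             perturb: Sequence[Tensor],
                             v: Sequence[Optional[Tensor]],
                             alpha_scale: float) -> List[np.ndarray]:
    """[ dG/d(wrt) ](perturb + a v) - same at (perturb - a v), over 2a."""
    norm = _flat_norm(v)
    if norm == 0.0:
        return [np.zeros_like(p.data) for p in wrt]
    alpha = alpha_scale / norm

    def grads_at(sign):
        for p, vi in zip(perturb, v):
            if vi is not None:
                p.data = p.data + sign * alpha * vi.data.astype(p.dtype)
        try:
            gs = grad(loss_fn(), list(wrt))
        finally:
            for p, vi in zip(perturb, v):
                if vi is not None:
                    p.data = p.data - sign * alpha * vi.data.astype(p.dtype)
        return [np.zeros_like(w.data) if g is None else g.data for g, w in zip(gs, wrt)]

    gp = grads_at(+1.0)
    gm = grads_at(-1.0)
    return [(p - m) / (2 * alpha) for p, m in zip(gp, gm)]


def arch_grad_audience_term(explainer, audience, arch: ArchitectureParams,
                            e_train: LabeledBatch, a_train: LabeledBatch,
                            a_val: LabeledBatch, config: LeaseConfig,
                            xi_e: float, xi_w: float) -> List[Tensor]:
    """Hypergradient of the audience's validation loss w.r.t. A through the
    three chained one-step maps A -> E' -> delta' -> W'.

    ``hypergrad="exact"`` evaluates the whole chain on one tape;
    ``hypergrad="fd"`` propagates a vector right-to-left through the three
    second-derivative factors, approximating each contraction with a
    symmetric finite-difference probe.
    """
    A = arch.tensors()
    e_weights = explainer.parameters()
    w_weights = audience.parameters()
    with nn.bn_stats_frozen():
        if config.hypergrad == "exact":
            e_over, _, _ = explainer_unroll(explainer, e_train, xi_e, create_graph=True)
            pert = generate_explanations(
                explainer, a_train, config.tau, config.xi_delta,
                steps=config.attack_steps, params=e_over,
                init=config.attack_init, attack_sign=config.attack_sign,
                rng=np.random.default_rng(config.seed), create_graph=True,
            )
            weighted = reweight_images(a_train, pert, mode=config.reweight_mode)
            w_over = audience_unrolled_step(audience, weighted, a_train.labels,
                                            xi_w, create_graph=True)
            val = audience_validation_loss(audience, a_val, params=w_over)
            out = grad(val, A)
            return [Tensor(np.zeros_like(a.data)) if g is None else g
                    for g, a in zip(out, A)]

        # -- finite-difference chain --------------------------------------
        _, _, gs = explainer_unroll(explainer, e_train, xi_e)
        e_prime = [Tensor(p.data if (g is None or xi_e == 0) else p.data - xi_e * g.data,
                          requires_grad=True)
                   for p, g in zip(e_weights, gs)]
        e_over = {id(p): ep for p, ep in zip(e_weights, e_prime)}

        sign = 1.0 if config.attack_sign == "ascent" else -1.0
        if config.attack_init == "uniform":
            rng = np.random.default_rng(config.seed)
            delta0 = rng.uniform(-config.tau, config.tau,
                                 size=a_train.images.shape).astype(a_train.images.dtype)
        else:
            delta0 = np.zeros_like(a_train.images)
        delta0_t = Tensor(delta0, requires_grad=True)
        x_at = Tensor(a_train.images)

        def attack_obj() -> Tensor:
            from .explanations import _divergence_from_logits

            z_orig = explainer(x_at, params=e_over)
            z_pert = explainer(x_at + delta0_t, params=e_over)
            return _divergence_from_logits(z_pert, z_orig)

        (g_delta,) = grad(attack_obj(), [delta0_t])
        step = delta0 + sign * config.xi_delta * (
            np.zeros_like(delta0) if g_delta is None else g_delta.data
        )
        delta_prime = np.clip(step, -config.tau, config.tau)
        interior = (np.abs(step) < config.tau).astype(delta_prime.dtype)

        dp_leaf = Tensor(delta_prime, requires_grad=True)

        def audience_train_obj() -> Tensor:
            weighted = reweight_images(
                a_train, PerturbationBatch(dp_leaf, config.tau),
                mode=config.reweight_mode,
            )
            return nn.cross_entropy(audience(weighted), a_train.labels)

        gw = grad(audience_train_obj(), w_weights)
        w_prime = [Tensor(p.data if g is None else p.data - xi_w * g.data,
                          requires_grad=True)
                   for p, g in zip(w_weights, gw)]
        w_over = {id(p): wp for p, wp in zip(w_weights, w_prime)}

        # v3 = dL_val/dW'
        val = audience_validation_loss(audience, a_val, params=w_over)
        v3 = grad(val, w_prime)

        # v2 = (dW'/dDelta')^T v3 = -xi_w * d2 O_W / dDelta' dW . v3
        probe = _probe_second_derivative(audience_train_obj, [dp_leaf],
                                         w_weights, v3, config.alpha_scale)
        v2 = -xi_w * probe[0]
        v2 = v2 * interior  # chain through the L-inf projection

        # v1 = (dDelta'/dE')^T v2 = sign * xi_delta * d2 O_att / dE' dDelta . v2
        probe = _probe_second_derivative(attack_obj, e_prime, [delta0_t],
                                         [Tensor(v2)], config.alpha_scale)
        v1 = [Tensor(sign * config.xi_delta * p) for p in probe]

        # final factor: (dE'/dA)^T v1 = -xi_e * d2 L_tr / dA dE . v1
        def train_loss_fn() -> Tensor:
            return nn.cross_entropy(explainer(Tensor(e_train.images)), e_train.labels)

        hv = fd_matvec(train_loss_fn, A, e_weights, v1, config.alpha_scale)
        return [Tensor(-xi_e * h.data) for h in hv]


# ---------------------------------------------------------------------------
# one search step and the outer loop
# ---------------------------------------------------------------------------


def lease_search_step(state: SearchState,
                      e_train: LabeledBatch, e_val: LabeledBatch,
                      a_train: LabeledBatch, a_val: LabeledBatch,
                      config: LeaseConfig,
                      opt_arch, opt_e, opt_w,
                      xi_e: Optional[float] = None,
                      xi_w: Optional[float] = None) -> SearchState:
    """One full four-stage update; mutates and returns ``state``.

    Stage 4 updates only the architecture variables; the committed optimizer
    steps for E (on its training loss, after the architecture moved) and W
    (on the explanation-reweighted images) follow, mirroring the alternating
    schedule of differentiable-NAS practice.
    """
    explainer, audience, arch = state.explainer, state.audience, state.arch
    xi_e = config.xi_e if config.xi_e is not None else (
        xi_e if xi_e is not None else opt_e.lr)
    xi_w = config.xi_w if config.xi_w is not None else (
        xi_w if xi_w is not None else opt_w.lr)
    A = arch.tensors()

    need_audience = config.objective_mode in ("combined", "audience_only")
    need_explainer = config.objective_mode in ("combined", "explainer_only")

    arch_grad = [np.zeros_like(a.data) for a in A]
    metrics: Dict[str, float] = {}
    weighted_data: Optional[np.ndarray] = None
    audience_involved = need_audience or config.gamma > 0

    with nn.bn_stats_frozen():
        if config.hypergrad == "exact":
            e_over, _, _ = explainer_unroll(explainer, e_train, xi_e,
                                            create_graph=True)
            objective = None
            if need_explainer:
                e_val_loss = nn.cross_entropy(
                    explainer(Tensor(e_val.images), params=e_over), e_val.labels
                )
                metrics["explainer_val_loss"] = float(e_val_loss.item())
                objective = e_val_loss
            if audience_involved:
                pert = generate_explanations(
                    explainer, a_train, config.tau, config.xi_delta,
                    steps=config.attack_steps, params=e_over,
                    init=config.attack_init, attack_sign=config.attack_sign,
                    rng=np.random.default_rng(config.seed + state.step),
                    create_graph=need_audience,
                )
                weighted = reweight_images(a_train, pert, mode=config.reweight_mode)
                weighted_data = np.array(weighted.data)
                w_over = audience_unrolled_step(audience, weighted, a_train.labels,
                                                xi_w, create_graph=need_audience)
                a_val_loss = audience_validation_loss(audience, a_val, params=w_over)
                metrics["audience_val_loss"] = float(a_val_loss.item())
                if need_audience:
                    term = config.gamma * a_val_loss
                    objective = term if objective is None else objective + term
            if objective is not None:
                gs = grad(objective, A)
                arch_grad = [np.zeros_like(a.data) if g is None else g.data
                             for g, a in zip(gs, A)]
        else:
            def train_loss_fn(params=None):
                return nn.cross_entropy(
                    explainer(Tensor(e_train.images), params=params), e_train.labels)

            def val_loss_fn(params=None):
                return nn.cross_entropy(
                    explainer(Tensor(e_val.images), params=params), e_val.labels)

            if need_explainer:
                gs = arch_grad_explainer_term(
                    train_loss_fn, val_loss_fn, explainer.parameters(), A,
                    xi_e, config.alpha_scale, mode="fd")
                arch_grad = [ag + g.data for ag, g in zip(arch_grad, gs)]
            if need_audience and config.gamma > 0:
                gs = arch_grad_audience_term(
                    explainer, audience, arch, e_train, a_train, a_val,
                    config, xi_e, xi_w)
                arch_grad = [ag + config.gamma * g.data
                             for ag, g in zip(arch_grad, gs)]
            if audience_involved:
                e_over, _, _ = explainer_unroll(explainer, e_train, xi_e)
                pert = generate_explanations(
                    explainer, a_train, config.tau, config.xi_delta,
                    steps=config.attack_steps, params=e_over,
                    init=config.attack_init, attack_sign=config.attack_sign,
                    rng=np.random.default_rng(config.seed + state.step))
                weighted = reweight_images(a_train, pert, mode=config.reweight_mode)
                weighted_data = np.array(weighted.data)

    for bad in arch_grad:
        if not np.all(np.isfinite(bad)):
            raise FloatingPointError("non-finite architecture gradient")

    # stage 4 commit: architecture step (never touches E or W)
    for a, g in zip(A, arch_grad):
        a.grad = g
    opt_arch.step()
    opt_arch.zero_grad()

    # committed weight steps on the training losses (fresh A)
    explainer.zero_grad()
    loss_e = nn.cross_entropy(explainer(Tensor(e_train.images)), e_train.labels)
    loss_e.backward()
    metrics["explainer_train_loss"] = float(loss_e.item())
    opt_e.step()
    opt_e.zero_grad()

    if weighted_data is not None:
        audience.zero_grad()
        loss_w = nn.cross_entropy(audience(Tensor(weighted_data)), a_train.labels)
        loss_w.backward()
        metrics["audience_train_loss"] = float(loss_w.item())
        opt_w.step()
        opt_w.zero_grad()

    combined = 0.0
    if "explainer_val_loss" in metrics:
        combined += metrics["explainer_val_loss"]
    if "audience_val_loss" in metrics:
        combined += config.gamma * metrics["audience_val_loss"]
    metrics["combined_objective"] = combined

    state.step += 1
    state.history.append({"step": state.step, **metrics})
    return state


def _iterate_batches(images: np.ndarray, labels: np.ndarray, batch_size: int,
                     rng: np.random.Generator):
    n = len(labels)
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        yield LabeledBatch(images[idx], labels[idx])


def run_search(splits: DataSplits, config: LeaseConfig,
               explainer=None, arch: Optional[ArchitectureParams] = None,
               audience=None,
               supernet_kwargs: Optional[dict] = None,
               audience_name: str = "resnet18",
               log_path=None) -> Tuple[Genotype, SearchState]:
    """Run the full search loop and return the derived genotype.

    Weight optimizers are SGD with momentum and weight decay under a cosine
    learning-rate schedule; the architecture optimizer is Adam. Networks may
    be passed in (tests) or are built from ``supernet_kwargs``.
    """
    from .audience import build_audience
    from .search_space import build_supernet

    if len(splits.part1) == 0 or len(splits.part2) == 0:
        raise ValueError("both data parts must be non-empty")
    in_channels = splits.part1.images.shape[1]
    num_classes = int(max(splits.part1.labels.max(), splits.part2.labels.max())) + 1

    if explainer is None:
        kw = dict(cells=8, init_channels=16, num_classes=num_classes,
                  in_channels=in_channels, seed=config.seed)
        kw.update(supernet_kwargs or {})
        explainer, arch, _ = build_supernet(**kw)
    if audience is None:
        _, audience = build_audience(audience_name, num_classes=num_classes,
                                     in_channels=in_channels, seed=config.seed + 17)

    state = SearchState(explainer=explainer, audience=audience, arch=arch)
    opt_arch = nn.Adam(arch.tensors(), lr=config.eta, betas=(0.5, 0.999),
                       weight_decay=config.arch_weight_decay)
    opt_e = nn.SGD(explainer.parameters(), lr=config.lr,
                   momentum=config.momentum, weight_decay=config.weight_decay)
    opt_w = nn.SGD(audience.parameters(), lr=config.lr,
                   momentum=config.momentum, weight_decay=config.weight_decay)

    epoch_rows = []
    for epoch in range(config.epochs):
        lr = nn.cosine_lr(config.lr, epoch, config.epochs, config.lr_min)
        opt_e.lr = opt_w.lr = lr
        rng = np.random.default_rng((config.seed * 100003 + epoch) % (2 ** 31))
        e_tr_iter = _iterate_batches(splits.part1.images, splits.part1.labels,
                                     config.batch_size, rng)
        a_tr_iter = _iterate_batches(splits.part1.images, splits.part1.labels,
                                     config.batch_size, rng)
        e_val_list = list(_iterate_batches(splits.part2.images, splits.part2.labels,
                                           config.batch_size, rng))
        a_val_list = list(_iterate_batches(splits.part2.images, splits.part2.labels,
                                           config.batch_size, rng))
        for i, (e_tr, a_tr) in enumerate(zip(e_tr_iter, a_tr_iter)):
            if config.steps_per_epoch is not None and i >= config.steps_per_epoch:
                break
            e_val = e_val_list[i % len(e_val_list)]
            a_val = a_val_list[(i + 1) % len(a_val_list)]
            lease_search_step(state, e_tr, e_val, a_tr, a_val, config,
                              opt_arch, opt_e, opt_w)
        state.epoch = epoch + 1
        eval_part = splits.part2
        if config.eval_subset is not None and config.eval_subset < len(eval_part):
            sub = rng.choice(len(eval_part), config.eval_subset, replace=False)
            eval_part = LabeledBatch(eval_part.images[sub], eval_part.labels[sub])
        acc, eval_loss = _evaluate_supernet(explainer, eval_part,
                                            max(config.batch_size, 64))
        recent = state.history[-1] if state.history else {}
        row = {
            "epoch": state.epoch,
            "search_val_accuracy": acc,
            "explainer_val_loss": recent.get("explainer_val_loss", float("nan")),
            "audience_val_loss": recent.get("audience_val_loss", float("nan")),
            "combined_objective": recent.get("combined_objective", float("nan")),
            "lr": lr,
        }
        epoch_rows.append(row)
    state.history_epochs = epoch_rows  # type: ignore[attr-defined]
    if log_path is not None:
        _write_csv(log_path, epoch_rows)
    vocab = explainer.vocab
    genotype = derive_genotype(arch, vocab, num_nodes=explainer.num_nodes)
    return genotype, state


def _evaluate_supernet(net, batch: LabeledBatch, batch_size: int) -> Tuple[float, float]:
    net.eval()
    correct, total, loss_sum = 0, 0, 0.0
    with no_grad():
        for start in range(0, len(batch), batch_size):
            xb = batch.images[start : start + batch_size]
            yb = batch.labels[start : start + batch_size]
            logits = net(Tensor(xb))
            pred = np.argmax(logits.data, axis=1)
            correct += int((pred == yb).sum())
            total += len(yb)
            loss_sum += float(nn.cross_entropy(logits, yb).item()) * len(yb)
    net.train()
    return 100.0 * correct / total, loss_sum / total


def _write_csv(path, rows: List[dict]):
    import csv

    if not rows:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
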