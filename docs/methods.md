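# Methods

This note documents the model implemented by `lease_nas`, the numerical
choices behind it, what the synthetic data emulates, and the limitations a
user should know about.

## The search problem

The package performs differentiable neural architecture search for 4-class
brain-MRI-style image classification. The searched model (the *explainer*)
is a cell-based supernet in the DARTS family: a stack of L cells, each a DAG
with 2 input nodes, 4 intermediate nodes and a concatenated output. Every
edge (j → i) carries a mixture of M = 8 candidate operations

    e_ji(x) = Σ_m  softmax(a_ji)_m · o_m(x),

with candidates: separable conv 3×3 and 5×5, dilated separable conv 3×3 and
5×5, max pool 3×3, average pool 3×3, identity, zero. The per-edge reals
a_jim are the architecture variables A — one `[14 × 8]` matrix for normal
cells and one for reduction cells (placed at depths ⌊L/3⌋ and ⌊2L/3⌋, where
channels double and edges from the cell inputs use stride 2). After search,
each edge keeps its strongest non-zero candidate and each intermediate node
its two strongest incoming edges (K = 2, "zero" excluded, ties to the lowest
index); the resulting genotype is stacked into a deeper network and trained
from scratch.

## Learning by self-explanation

The architecture is *not* updated by its own validation loss alone. A second,
fixed-architecture model (the *audience*, ResNet-18 by default) is trained on
images reweighted by the explainer's saliency explanations, and the
audience's validation loss becomes part of the architecture objective. One
search step runs four stages on four minibatches (explainer train/val,
audience train/val — in practice the two models share the same two halves of
the training pool):

1. **Explainer unroll** E′ = E − ξ_e ∇_E L(E, A; D_e^tr), one plain gradient
   step on the explainer's training cross-entropy.
2. **Explanation** For each audience training image x, a perturbation δ with
   ‖δ‖_∞ ≤ τ is moved one projected gradient step up the divergence
   ℓ(f(x+δ; E′), f(x; E′)), where ℓ is cross-entropy between the two
   predictive distributions. Pixels supporting large useful perturbations
   are the decision-relevant ones.
3. **Audience unroll** W′ = W − ξ_w ∇_W Σ ℓ(f(δ′ ⊙ x; W), t): one plain
   gradient step on explanation-reweighted images.
4. **Architecture update** A ← A − η ∇_A [ L(E′, A; D_e^val) +
   γ L(W′; D_a^val) ]. The gradient is a hypergradient through the three
   unrolled one-step maps.

After stage 4, the explainer and audience commit one *real* optimizer step
each (SGD, momentum 0.9, weight decay 3e-4, cosine-annealed learning rate
from 0.025) on their own training losses; the architecture optimizer is Adam
(lr 3e-4, betas 0.5/0.999, weight decay 1e-3). The unrolled stage-1/2/3 maps
deliberately exclude momentum and weight decay so their derivatives are the
literal second-derivative factors; ξ_e and ξ_w default to the current
learning rates of the corresponding real optimizers.

### Hypergradient evaluation

Two interchangeable evaluation paths are provided (`hypergrad=`):

* `exact` (default): reverse-mode differentiation through the whole
  four-stage graph. This includes every dependence on A — also the direct
  appearance of A in the stage-2/3 forward passes — and is verified against
  coordinate-wise central differences of the fully unrolled objective
  (tests; relative error ~1e-7 on a sub-200-parameter supernet).
* `fd`: the chain of symmetric finite-difference contractions
  (∂E′/∂A)(∂Δ′/∂E′)(∂W′/∂Δ′)∇_{W′}L, each second-derivative factor
  approximated by two extra gradient evaluations at points displaced by
  ±α·v with α = `alpha_scale`/‖v‖₂ (default numerator 0.01). This is the
  memory-lean variant; it follows the printed chain rule, which routes
  through E′ only, so it omits the direct-A paths that `exact` includes.
  With `objective_mode="explainer_only"` it reproduces the classic
  second-order DARTS update exactly (verified entry-wise to float
  precision).

Probe accuracy: symmetric differences are exact on quadratics for any α (a
property the tests exploit), but with piecewise-linear activations (ReLU,
max-pool) a probe of size 0.01/‖v‖ can cross activation kinks; on tiny
float64 verification networks the tests therefore use `alpha_scale=1e-5`,
where the probes agree with exact autodiff to ~1e-12. The 0.01 default is
kept for fidelity to standard second-order NAS practice at float32 training
scale.

### Perturbation initialization

δ is initialized uniformly in [−τ, τ] (the attack "adds small random
perturbations"). A zero initialization is available (`attack_init="zeros"`)
but degenerate for a one-step attack: the divergence ℓ(f(x+δ), f(x)) is
minimized at δ = 0, so its gradient there vanishes identically, the step
returns δ′ = 0, and the audience would train on all-zero images x ⊙ 0. The
default τ is 0.1 on [0,1]-scaled pixels; reweighting uses the raw signed
product x ⊙ δ (the literal training objective of the audience), with a
documented variant `reweight="abs_norm"` (x ⊙ |δ|/max|δ|) that preserves
image polarity.

Ascent/descent: the explanation objective is a maximization, so the step
ascends the divergence by default; `attack_sign="descent"` applies the
opposite sign for comparison, since the one-step update is sometimes written
with a minus sign in the unrolled-approximation literature.

## Execution engine

No deep-learning framework is used: the package carries a self-contained
reverse-mode autodiff engine over NumPy arrays (`lease_nas.autograd`) in
which every primitive's vector-Jacobian product is itself built from
primitives, so gradients can be re-differentiated (`create_graph`) — the
mechanism behind the exact hypergradient and the exact second-derivative
contractions used as test oracles. Convolutions are im2col + matmul with a
strided `unfold`/`fold` adjoint pair; in the supernet, all edges entering a
node with equal stride are evaluated as one stacked-channel tensor per
candidate operation (depthwise convolutions and batch norm act per channel,
so stacking is exact; pointwise 1×1 convolutions become a batched matmul).
This is purely an execution layout for CPU efficiency and changes nothing
about the mixture semantics.

Batch-norm layers use batch statistics during training (kept on the tape, so
unrolled steps differentiate through them) and running statistics in
evaluation mode; running statistics are updated only by committed training
passes, never by unrolled or probe passes.

## Synthetic data

Real brain MRI cannot be redistributed with the package, so the study
conditions are emulated: an elliptical "brain" (tissue intensity 0.35 on
background 0.03) with a class-specific bright structure (intensity 0.95) —
an irregular interior blob in the upper half (glioma-like), a crescent
hugging the rim (meningioma-like), a small bottom-centre focus
(pituitary-like), or nothing (healthy) — plus a random rotation of ±15° and
Gaussian pixel noise (default sd 0.05). Default per-class counts follow the
study layout: 2870 training and 394 test images at 64×64.

Classes are recoverable by construction: a hand-coded rule (brightest-pixel
radial extent and centroid height) classifies noiseless images perfectly at
the default 64×64 (and down to ~32 px; below that, pixel discretization
erodes the geometric margins, and the generator's minimum spot size keeps
lesions visible rather than the margins exact). The generator does **not**
emulate scanner physics, intensity inhomogeneity, anatomical variability, or
inter-class texture differences — passing tests show the pipeline learns
separable geometric structure end-to-end, not that it reaches clinical
accuracy on real MRI.

Splitting is label-stratified: part 1 of a 50/50 split serves as training
data for both explainer and audience, part 2 as both validation sets. The
evaluation phase trains on the full training pool. AutoAugment is not
reimplemented; an augmentation hook accepts user transforms (default:
horizontal flip + small rotation).

## Metrics

Accuracy, precision, recall, F1 and specificity are computed from the
confusion matrix one-vs-rest per class and macro-averaged (unweighted mean;
the micro/macro choice and the multi-class AUC scheme are this package's
documented choice). AUC is one-vs-rest per class with midrank tie handling;
classes absent from the labels are excluded from the macro AUC with a
warning. Argmax ties resolve to the lowest class index. All values are
percentages.

## Desk-scale configurations

A full-scale search (8 cells, 16 channels, 64×64, 50 epochs, then a 12-cell
36-channel retraining) is supported by the code and configuration but is a
GPU-month-class computation on this CPU engine. The shipped verification
runs therefore use reduced problem sizes, chosen once as the package's
desk-scale study conditions:

* hypergradient oracles: a 2-cell, 1-node, sub-200-parameter supernet on
  4×4 inputs (small enough for exhaustive coordinate-wise differentiation);
* end-to-end: 16×16 images, 200 per class, a 4-cell/4-channel supernet
  searched for 10 epochs with one four-stage step per epoch
  (`steps_per_epoch=1`, batch 16, arch lr 3e-3, `small_cnn` audience),
  followed by a 2-cell/4-channel retraining for 20 epochs — repeated over 3
  seeds. The per-epoch validation metrics are computed on a 128-image
  subsample.

`steps_per_epoch` trades arch-update frequency against wall-clock time; at
full scale the conventional one step per minibatch (`None`) applies.

## Known limitations

* CPU-only and NumPy-based: roughly two orders of magnitude slower than a
  GPU framework; full-scale searches are impractical.
* The exact hypergradient holds the whole four-stage tape in memory
  (~4.5 GB at the toy scale, scaling with batch size); the `fd` path trades
  ~2× time for ~2× less memory.
* One A-update per weight-update and a persistent (not re-initialized)
  audience are fixed conventions of this implementation; both are exposed
  in code but not swept.
* Max pooling treats zero-padded borders as zeros (not −∞); all cell inputs
  pass through BN/ReLU first, matching common supernet implementations.
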