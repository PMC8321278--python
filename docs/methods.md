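# Methods

## Model

The segmenter is a U-shaped fully convolutional network. Each resolution
level applies two 3×3 same-padded convolutions, one batch-normalization
layer after the pair, and a rectifier; the encoder halves resolution with
2×2 max pooling while doubling channels (`base_filters · 2^level`), and the
decoder mirrors it with 2×2 stride-2 transposed convolutions and skip
concatenations from the encoder at matching resolution. A 1×1 convolution
and per-pixel softmax produce the `c`-class probability field. Same padding
keeps the output aligned pixel-for-pixel with the input, so dice and
acquisition maps cover the whole image; the cost is that border pixels see
zero padding inside their receptive field.

Stochasticity is Bernoulli dropout (inverted scaling, element-wise with
rate `p`) at placements selected by `ModelConfig.variant`:

| variant            | dropout sites                                   | count  |
|--------------------|--------------------------------------------------|--------|
| `plain`            | none                                             | 0      |
| `maxpool_dropout`  | immediately after each max pool                  | depth  |
| `standard_dropout` | after every double-convolution block             | 2·depth+1 |
| `both`             | union of the two                                 | 3·depth+1 |

`maxpool_dropout` is the default: placing dropout only after pooling
perturbs the low-resolution feature maps, which benchmarks as the best
compromise between uncertainty quality and training stability.

## Inference

*Standard prediction* is one forward pass with every dropout site disabled
and batch norm on its frozen running averages — deterministic and
bit-reproducible. *MC prediction* keeps dropout live and averages `T`
passes (fresh masks per pass from one seeded generator); the full `T`-slice
stack is retained so disagreement statistics can be formed. Per-pixel
predictive variance is the variance across passes of the probability of the
MC-mean argmax class. Monte-Carlo batch normalization (re-estimating batch
statistics per stochastic pass) exists behind the `mc_batchnorm` flag but
is off by default: dropout is the default uncertainty source, since there
is no canonical protocol for choosing the statistics batch at inference.

`T` defaults to 20. On a network without dropout sites MC prediction
degenerates gracefully: all passes equal the deterministic pass and the
predictive variance is exactly zero (agreeing passes are zeroed explicitly
so no floating-point residue survives).

## Acquisition functions

All four scores reduce an image to a non-negative scalar in nats by summing
a per-pixel quantity; rankings are invariant to the log base.

- entropy: −Σᵢ pᵢ ln pᵢ of a probability map (the MC mean), pixel-summed.
- BALD: H[mean over passes] − mean over passes of H[pass], pixel-summed;
  non-negative by Jensen's inequality.
- committee KL: KL(standard ‖ MC mean), pixel-summed.
- committee JSD: ½KL(p‖m) + ½KL(q‖m), m = (p+q)/2 — symmetric, per-pixel
  bounded by ln 2.

Numerics: 0·ln 0 is evaluated exactly as 0 via `scipy.special.xlogy`; only
log *denominators* are floored at ε = 10⁻¹², which keeps KL finite on
disjoint support without perturbing the exact closed forms (uniform binary
entropy, opposing-one-hot BALD and disjoint-one-hot JSD all equal ln 2 to
machine precision). Image scores are floored at 0 against roundoff. The
divergence pair aggregates pixels by SUM, mirroring the explicit pixel-sum
definition of the entropy pair; sum vs mean only matters if image sizes
differ within one pool.

Selection is top-k by score with ties broken toward the smallest image id,
clamped to the pool size.

## Active-learning loop

`run_active_learning` executes: seeded uniform draw of the initial labelled
set (default 2) → oracle query → initial training → repeat {score a
(sub)sample of the pool, query the oracle for the top k (default 2), fold
labels in, warm-start retrain} until the iteration budget (default 15) or
pool exhaustion. Weights are refined across iterations, never
re-initialized. The `random` acquisition draws scores uniformly and is the
control baseline for efficacy claims. `subsample_size` defaults to the
whole pool. Per-iteration history records labelled count, MC-validation
dice mean/sd, epochs trained and wall seconds.

Training is Adam at lr 0.001 on mean categorical cross-entropy, mini-batch
4, with early stopping on deterministic validation dice: stop after
`patience` (default 5) epochs without improvement within a `max_epochs`
budget (default 60, reflecting that generalization on these tasks sets in
well below 60 epochs), then restore the best-epoch snapshot. `max_epochs=0`
is an explicit no-op so warm-start behaviour is verifiable. A fixed
held-out validation set is used throughout a run.

## Metrics

Binary dice 2TP/(2TP+FP+FN); the 0/0 case (both masks empty) is defined as
1.0 and tested. Multi-class dice is the macro average of one-vs-rest binary
dice over classes present in the ground truth — averaging over absent
classes would reward predicting nothing; background participates like any
class. Micro-averaging is the main alternative; macro was chosen so rare
classes weigh equally, and the choice is stated so numbers are comparable.

## Synthetic data

`generate_dataset` renders `n_images` of H×W (default 64×64, divisible by
2^depth) with 2–5 random objects (discs, rectangles, rings) per image.
An object's class (1…c−1) fixes its intensity `label/(c−1)`; the rendered
geometry is the exact mask; additive Gaussian noise (default sd 0.05, on a
[0,1] intensity scale) sets difficulty. The default preset uses c = 5
classes — multi-class enough to exercise class-rich behaviour, small enough
for CPU training. With flat (texture-free) rendering, classes beyond 256
would collide in 8-bit intensity bands and are rejected.

This emulates multi-class structure, class–intensity correlation and shape
variety; it does **not** emulate real microscopy texture, staining
variation, touching-object ambiguity or annotation noise. Passing tests
demonstrate the machinery (uncertainty, acquisition, budget accounting) at
desk scale, not performance on real histology or cell-tracking data.

The augmentation family applies one random affine map — rotation, shift,
scale, shear sampled from configurable ranges — identically to image
(bilinear) and mask (nearest-neighbour, so labels stay integral);
out-of-frame regions are filled with background. The expected foreground
fraction has a closed-form approximation (independent uniform placement:
1 − (1−f̄)^k̄ with exact per-shape expected areas) used as a generator
sanity check at ±20%.

## Experiment scale

The reduced efficacy protocol (`abunet.experiments`) uses a depth-2,
8-filter network on 5-class 64×64 images: pool 40, validation 10, initial
2, k = 2, 5 iterations, T = 10, `max_epochs` 8 with patience 3, across 5
paired seeds (both acquisition arms share each seed's dataset, network
initialization and initial labelled set, a variance-reduction pairing).
These sizes keep a full comparison within minutes on one CPU while leaving
enough learning signal for the directional claim — committee-JSD final
MC-validation dice at least matching random selection at an equal label
budget. The full-size protocol (15 iterations, 60-epoch budget, larger
networks) is the same code with larger arguments.

## Numerical engine

The network runs on a compact reverse-mode tape autodiff over NumPy
(float32 parameters and activations; softmax and all acquisition math in
float64). Convolutions are stride-1 same-padded correlations via im2col +
BLAS matmul, with the input gradient computed as a correlation with the
channel-swapped, spatially flipped kernel; 2×2/stride-2 transposed
convolutions reduce to reshapes because their windows do not overlap; max
pooling routes gradients through stored argmax indices (ties take the first
maximum). Batch norm uses mini-batch statistics with the full training-mode
gradient and momentum-0.1 running averages for inference. The whole engine
is validated against central finite differences in float64 (worst relative
error ~1e-4, consistent with finite-difference noise).

## Known limitations

- Border pixels are systematically less reliable (zero padding).
- An untrained or under-trained network's MC mean converges slowly in T
  (per-pass std ~0.3); uncertainty maps are meaningful only after training.
- Checkpoints store float32 weights; determinism guarantees hold within one
  BLAS/NumPy build.
- The oracle simulation returns perfect masks; annotation noise is out of
  scope.
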