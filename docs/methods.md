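# Methods

## The model

`ganseg` implements an adversarial multi-organ segmentation model for 2-D
grayscale images with two players:

* **Generator** — a bottleneck residual backbone (7x7 stride-2 stem with
  3x3 stride-2 max pooling, then four stages of 1x1/3x3/1x1 bottleneck
  blocks with shortcut connections, expansion 4, block counts 3/4/6/3).
  The four stage outputs (strides 4/8/16/32) are reduced to a common
  branch width by 1x1 convolution + batch norm + ReLU, bilinearly
  upsampled to the stride-4 grid and fused by channel concatenation
  followed by a 3x3 and a 1x1 convolution.  Four branch heads — one per
  backbone stage — concatenate the fused map with their stage map, apply
  *dual non-local attention* (sum of a spatial position-position head and
  a channel-channel head, each a residual block), project to the K class
  channels, upsample to the input grid and take a per-pixel softmax.  The
  final prediction averages the four branches ("Branch averaging" below).
* **Discriminator** — a plain CNN (five 3x3 stride-1 conv + ReLU + 2x2 max
  pool blocks, two fully connected layers, sigmoid) that scores
  *organ-masked images*: the segmentation's K-1 foreground channels
  multiply the image element-wise, isolating each organ's appearance.
  Gold-standard masks use one-hot labels; predictions are masked with soft
  probabilities so the adversarial gradient reaches the generator.

Non-local attention computes, for every position j, a softmax-normalised
affinity over all positions i from projected dot products
theta(x_i)·phi(x_j) (equivalently, the normalised embedded-Gaussian
kernel), then averages the value projections g(x_i) by those weights.  The
projections run at T = max(1, floor(C/4)) channels; a 1x1 output weight
restores C channels before the residual addition, so zeroed output weights
make each head an exact identity.  The channel head scores raw reshaped
feature channels against each other (no theta/phi projection) and applies
one 1x1 output weight.  Gaussian, embedded-Gaussian, plain dot-product and
cascaded (concatenation) affinity kernels are all available in
`ganseg.attention`; the model path uses the dot-product + column-softmax
form.

## Losses and training

The generator minimises the multi-class pixel cross-entropy against the
gold standard plus, weighted by lambda (default 0.2), a binary
cross-entropy asking the discriminator to call its masked prediction real.
The discriminator minimises the usual real/fake binary cross-entropy.
Training alternates k = 6 discriminator updates with one generator update
(minibatches of 10, drawn without replacement from separate shuffled
streams), using plain minibatch gradient descent at eta = 0.01 and
truncated-normal weight initialisation (clipped at 2 sigma); biases start
at zero and batch-norm scales at one (a zero-centred random scale would
extinguish the signal at initialisation).

**Initialisation scale.** The per-layer sigma is fan-in-scaled by default
(sqrt(2/fan_in), the standard ReLU-preserving choice;
``TrainConfig.init_scheme="fixed"`` reverts to a single global sigma,
default 0.02).  The fixed small sigma is pathological for the
discriminator: five convolution layers each attenuate the signal by a
factor ~0.02·sqrt(fan), so the sigmoid input is ~1e-5 and the
discriminator sits frozen at output 0.5 — the adversarial term is then a
constant and contributes nothing.  With fan-in scaling the discriminator
is alive from the start and the alternating game behaves as designed: the
discriminator quickly learns to spot missing small organs in the masked
prediction, and the adversarial gradient is precisely what accelerates
the generator on those classes.

**Loss scale.** The classical pixel-summed cross-entropy grows linearly
with image area, so a learning rate is only meaningful relative to a loss
scale: the pair (eta, reduction) is under-determined when eta alone is
given.  At 64x64 and eta = 0.01 the summed form (scale H·W) oscillates so
violently that training collapses to the background class within one
epoch, while the pure pixel mean (scale 1) is stable but converges an
order of magnitude too slowly for desk-scale schedules — small organ
classes surface only after thousands of generator updates.  The training
loop therefore optimises the area-normalised objective times a fixed gain,

    G_train = gain · [L_mec_sum + lambda · L_bec] / (H·W),

with ``TrainConfig.loss_gain`` defaulting to 32.  The gain is a pure
rescaling of the whole objective (lambda keeps exactly its balancing
role); at the reference eta = 0.01 it places plain MBGD in the regime
where training is both stable and converging at desk scale — gains from
16 to 32 behave equivalently up to time scale, with convergence time
roughly inversely proportional to the gain.  During development we also
observed
the mixed form (mean cross-entropy + *unscaled* adversarial term)
destabilise as soon as the discriminator starts winning, because the
adversarial per-pixel gradient then outweighs the cross-entropy per-pixel
gradient by a factor of H·W — a useful caution for anyone re-deriving the
scaling.  `multiclass_ce` itself defaults to the classical summed
definition; the reduction is a parameter.

**Branch averaging.** The four branch predictions can be combined on the
probability scale (mean of the four softmax maps) or on the logit scale
(softmax of the mean logits).  The probability mean looks natural — the
result is a convex combination of valid probability maps — but it acts as
a majority veto: a class wins the argmax only once *most* branches assign
it mass, and the deeper branches (whose own feature maps carry little
spatial detail) learn small classes much later than the stride-4 branch.
In desk-scale runs the stride-4 branch reached kidney-analog Dice of
0.8-0.9 while the probability-averaged output was still at 0.0.  Logit
averaging lets one confident branch carry a class, so it is the default
(``GeneratorConfig.average_logits = True``); the probability mean remains
available for comparison.

**Checkpoint selection.** When a validation set is supplied, training
keeps the generator snapshot with the best validation mean foreground Dice
alongside the final state; evaluation uses that snapshot.  Plain SGD shows
occasional transient dips in held-out Dice, and checkpoint selection — not
early stopping — is how the package handles them.

Backpropagation uses the package's own reverse-mode autodiff tape over
numpy arrays (`ganseg.autodiff`, `ganseg.nnops`: im2col convolution,
windowed max pooling, separable bilinear interpolation matrices, fused
softmax and batch norm).  Analytic gradients are pinned by
central-difference conformance checks at three levels: every primitive,
small composite stacks, and the full generator/discriminator losses.  The
full-model check adapts its step size per coordinate (1e-6 down to 1e-9)
because a deep batch-normalised network mixes stiff directions — where a
large step's truncation error dominates — with nearly flat ones, where a
small step drowns in round-off; the relative-error denominator is floored
(1e-6) so that essentially-zero gradients are compared absolutely, the
convention mainstream numerical grad-checkers use.

Gradient isolation between the two players is structural: the
discriminator loss detaches the generator's output, and each training
round steps only its own parameter registry, so the other player's
parameters are bit-for-bit unchanged.

## Synthetic phantoms

The phantom generator renders, per seeded sample: one large bright liver
analog (class 1, 7-12 % of the image area), two small lateral kidney
analogs (classes 2-3, 1-2.2 %), and one medium spleen analog (class 4,
3-5 %) as jittered ellipses in anatomically inspired placement regions on
a dark background (intensity 0.10); organ mean intensities (0.85, 0.40,
0.55, 0.70) are pairwise separated by at least twice the noise standard
deviation (0.05).  A smooth multiplicative bias field (amplitude 0.10,
Gaussian-filtered noise) emulates MRI coil inhomogeneity and additive
Gaussian noise corrupts the image; the label map is the exact pre-noise
geometry.  Augmentation is restricted to 90-degree rotations and axis
mirrors so labels transform without interpolation; arbitrary-angle
rotation is deliberately excluded from the default pipeline.  Splits are
disjoint by phantom identity.

What the phantoms do *not* emulate: anatomical shape variability beyond
ellipses, partial-volume soft boundaries, organ contact/overlap, slice-to-
slice 3-D context, and scanner-specific noise statistics.  Passing the
end-to-end recovery test therefore demonstrates that the full adversarial
pipeline can learn a multi-class, class-imbalanced segmentation with known
ground truth — not clinical-grade performance on real MRI.

## Problem sizes

Everything runs at two presets.  The `paper` preset mirrors the reference
conditions (256x256 images, width-64 generator, 200 epochs) and is
GPU-scale; it exists for completeness.  The `desk` preset — width-8
generator, 64x64 phantoms, discriminator widths 16/32/64/128/256 — is the
default and what all tests use.  The end-to-end recovery test and the
acceptance script train the desk preset with the reference hyperparameters
(eta = 0.01, k = 6, lambda = 0.2, batch 10) on 200 phantom identities
expanded fourfold (800 training samples), with 20 validation phantoms for
checkpoint selection, for 6 epochs (480 generator / 2880 discriminator
updates); 20 held-out phantoms are scored with the background-excluded
metric suite.  Under these conditions held-out mean foreground Dice
reaches the high 0.8s with every organ-analog class at or above ~0.8
(exact values are what `scripts/acceptance.py` recomputes).

## Evaluation conventions

Per class: recall, precision, F1, Dice (= F1 identically) and IoU from
one-vs-rest pixel counts.  Aggregates are unweighted means over foreground
classes only; overall pixel accuracy (background included) and mean
foreground recall are reported separately under explicit names because
"accuracy" is ambiguous between them in common usage.  Empty classes:
absent from truth and prediction scores 1.0; absent from truth but
predicted scores 0.0.  Confusion matrices print in row-percentage form
(rows = truth, summing to 100).

## Numerical choices

* Probabilities are clamped to [1e-7, 1 - 1e-7] before any logarithm.
* Column softmax subtracts the column maximum before exponentiation.
* Argmax ties in label-map inference resolve to the lowest class index.
* Bilinear interpolation uses half-pixel centres with edge clamping
  (align-corners-false convention), realised as two small dense
  interpolation matrices so forward and adjoint are plain matmuls.
* Batch norm uses biased batch variance, eps 1e-5, momentum 0.1 running
  statistics (training mode) and the stored statistics in eval mode.
* float32 is the training default; gradient-conformance tests run the
  model in float64.
* Deterministic mode fixes all seeds and forces single-threaded BLAS
  reductions; checkpoint resume is then bitwise identical to an
  uninterrupted run when the batch size divides the dataset size.

## Known limitations

* Plain MBGD with the reference learning rate converges slowly on
  class-imbalanced data: small organ classes emerge only after several
  hundred generator updates (the reference schedule provides thousands).
  The desk-scale tests size their schedules accordingly.
* The discriminator starts nearly silent: with sigma = 0.02 weights, five
  conv layers attenuate activations so its early outputs sit at 0.5 and
  adversarial pressure grows only gradually.  This matches the alternating
  protocol's intent (the discriminator trains 6x more often) but means
  short runs are dominated by the segmentation loss.
* 2-D only; no surface-distance metrics; no pretrained backbones.
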