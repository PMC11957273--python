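# Methods

## Spline-edge layers

Every KAN edge function is a linear combination of B-spline basis functions
plus a weighted base activation:

    φ(x) = w_base · σ(x) + s · Σ_m c_m B_m(x).

**Grid.** The basis lives on a uniform knot grid with G intervals on
[lo, hi] and degree k; k extension knots per side replicate the interior
spacing, giving G + 2k + 1 knots and G + k basis functions.  The default
domain is [−1, 1] with G = 5, k = 3 (cubic).  The domain choice reflects
where the layer's inputs actually live: one-hot DNA channels are 0/1 and
batch-normalized activations concentrate near zero with unit scale.  Both
bounds, G and k are configurable per layer.

**Evaluation.** The plain-numpy path runs the iterative (vectorized)
Cox–de Boor recursion; the autodiff path is a single fused primitive whose
backward pass multiplies by the analytic derivative basis
(d/dx B_{m,k} expressed through degree-(k−1) basis functions).  Higher
derivative orders recurse through the same primitive, so second-order
gradients are available without retaining the recursion's intermediates.
Inputs outside the grid domain are evaluated by the same recursion (basis
rows then sum to less than one) rather than clamped; this keeps the layer
differentiable everywhere during training.  A `clamp_inputs` flag clips to
the domain when hard boundaries are wanted.  At the right domain boundary
the last interior interval is treated as closed so the partition of unity
holds at x = hi exactly.

**Initialization.** Base weights use a variance-preserving uniform scheme
(bound √(6/fan_in)); spline coefficients start as small noise with scale
0.1/(G+k) so the spline branch begins near zero and the layer behaves like
its standard counterpart early in training; the per-edge scaler starts at 1.
Each layer's RNG stream is keyed by (seed, layer name), so replacing one
sub-layer never shifts the initialization of any other layer — this is what
makes baseline-vs-KAN comparisons differ only where the architecture does.

**Regularization.** The sparsity penalty is
`l1_weight · mean|c| + entropy_weight · H(p)` with p the normalized
per-edge L1 norms; it is zero exactly when the spline branch vanishes.

**Cost accounting.** `count_parameters` is exact (linear KAN:
`n_out·n_in·(G+k)` spline + `n_out·n_in` base + optional `n_out·n_in`
scaler; KAN layers carry no bias).  `estimate_flops` counts fused
multiply–adds analytically: bias additions and pointwise activations are
excluded, and basis evaluation is charged (k+1)·k recursion steps per input
scalar.  These are modeling conventions, documented so ratios (KAN vs
standard layer) are meaningful; they are not profiler measurements.

## Architectures

**Classifier.** A LegNet-style CNN: 7-wide conv stem → N residual blocks
(5-wide conv → batch norm → SiLU → squeeze-excitation → pointwise conv →
batch norm → SiLU → residual add) → pointwise final conv → global average
pool → dense head.  The SE mid-block pools channels and passes them through
a gated two-branch linear bottleneck (`a(z) · sigmoid(b(z))`) before
expanding to a sigmoid channel scale; "bilinear" here means the product of
two linear maps — an upsampling interpretation was considered and rejected
because the block operates on pooled channel vectors, which have no spatial
axis to resample.  Variants: `lkan` replaces the three SE linear maps with
linear KANs in the last `replaced_blocks` blocks; `ckan` replaces the stem
and final convolutions with KAN convolutions; everything else is identical
across variants (assertable on the text layer manifest).  Defaults (6
blocks, 32 channels) give ~45k (baseline) to ~86k (fully replaced LKAN)
parameters — deliberately desk-scale; `match_parameter_budget` scales
channel widths by binary search to equalize any two variants within 2%.
The classifier head (average pooling, no dropout) is a documented default,
not a claim of fidelity to any particular published configuration.

**WGAN.** Generator: dense latent→(C×L) map, five residual blocks (5-wide
conv, padding 2, ReLU), pointwise conv to 4 nucleotide-logit channels.
Critic: mirror structure with a pooled two-layer dense head.  `lgan` swaps
the critic head for linear KANs, `cgan` swaps the residual-block
convolutions (generator and critic) for KAN convolutions.  Training uses
the gradient penalty form of the Lipschitz constraint by default (penalty
weight 10, several critic steps per generator step) because it is stable at
small scale; original-style weight clipping is selectable.  The critic is
norm-free, as is standard when penalizing gradients.  Generator outputs are
decoded by per-position argmax (deterministic) or temperature-1 categorical
sampling; the softmax relaxation (not hard one-hot) is fed to the critic
during training so gradients reach the generator.

## Synthetic flipon benchmarks

The generator emulates binary non-B-DNA detection tasks.  Background is
iid with P(G)=P(C)=gc/2 (default GC 0.41, the human genome-wide value) or
a first-order chain with 0.3 persistence.  Positives carry one planted
signature, each planted position following its class rule independently
with probability `motif_strength` (default 0.9):

- **zdna**: strict purine/pyrimidine alternation, G/C favoured 3:1 within
  each class (Z-DNA forms most readily on (GC)n steps);
- **g4**: four G-runs (≥3 nt) with 1–7 nt loops packed into the motif
  window;
- **hdna**: a homopurine arm, ≤4 nt spacer, and its mirror image;
- **diffuse**: motif_length/4 copies of a weak 4-mer scattered uniformly —
  a proxy for signals without a crisp motif;
- **none**: no signal (labels independent of sequences; any classifier's
  expected MCC is 0).

Motifs are planted on the forward strand; a reverse-complement option
exists but is off by default since these signatures are nearly
strand-symmetric.  Duplicate handling is exact-string deduplication before
splitting — sufficient at synthetic scale but deliberately weaker than the
homology-aware leakage control real genomic benchmarks need.  Fold
assignment is stratified by label with fold sizes within one sequence.

What passing tests on this generator do **not** show: robustness to the
near-duplicate structure, compositional biases and label noise of real
flipon datasets (experimental Z-DNA/G4/H-DNA maps), or behaviour at
genome-scale sequence lengths.  The generator establishes that the
machinery learns plantable signals with the expected monotonicity in
signal strength, nothing more.

## Training and evaluation

Optimizer: AdamW (decoupled weight decay), lr 3e-3 for classifiers, 1e-4
with betas (0.5, 0.9) for GANs.  Within each training fold, a stratified
10% validation split drives early stopping (patience on validation loss,
or a `stop_at_val_mcc` target for stop-when-solved runs).  EMA of weights
(shadow ← d·shadow + (1−d)·w) is available; decay 0 tracks raw weights and
decay→1 freezes the shadow, which the tests pin down.  MCC uses the
convention 0 when any confusion marginal is empty; ROC-AUC with a single
class present is reported as undefined (None), never 0.5.  Hard-label
metrics threshold the positive-class probability at 0.5.

The ablation sweep trains one model per (G, N) cell and reports F1 (test
and train, and their gap as an overfit indicator), the exact parameter
count and wall-clock per batch.  Timing is hardware-dependent and excluded
from any assertion; the parameter column's strict growth in G is asserted.

Desk-scale problem sizes used throughout the test suite and acceptance
script — classification at n = 2000, length 200, ≤ 5 epochs; ablations at
n = 400, length 80; WGAN at 300 steps on 500 sequences of length 60 — are
the package's chosen study conditions for single-CPU reproducibility.

## Generation metrics

Edit distances are unit-cost Levenshtein (edlib's alignment distance; no
affine gaps).  D_self: mean nearest-neighbor distance within a sampled set
(default sample 1000, without replacement, seeded); D_train: mean distance
from generated to nearest training sequence.  Reports always include
D_self of the real training set as the diversity reference.  The
distributional distances are interpretations, since "KL divergence and
Wasserstein distance between real and synthetic data" underdetermines the
feature space: KL is computed on pseudocounted k-mer distributions
(k = 3 default) and the 1-D Wasserstein on per-sequence GC content
(quantile-coupling formula); both feature choices are configurable.

## Numerical engine

All layers run on a small reverse-mode autodiff engine over float64 numpy
arrays.  Convolution is a closed family of three mutually-adjoint
primitives (forward correlation, input-gradient, weight-gradient), each
looping only over the kernel axis and delegating to BLAS.  VJPs of
transcendental ops multiply by precomputed derivative arrays, keeping the
graph cycle-free (prompt memory release); consequently second-order
gradients flow exactly through the polynomial/piecewise-linear op family —
conv, matmul, arithmetic, relu — which covers the Wasserstein critic, the
one place double backprop is needed.  Degenerate-input policy: non-finite
inputs to layers raise immediately; non-finite losses raise a divergence
error carrying the last good weights.

## Known limitations

- No GPU path and no adaptive/data-driven knot refinement; grids are fixed
  and uniform.
- Second-order gradients are not propagated through sigmoid/tanh/exp
  (documented engine trade-off; irrelevant to the norm-free critic).
- The diffuse class is a weak-signal proxy, not a model of any specific
  functional element.
- Edit-distance metrics are O(n²) in the evaluated sample; use `n_eval`
  to bound cost on large sets.
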