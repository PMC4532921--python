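# Methods

`divrbm` trains binary restricted Boltzmann machines (RBMs) on preprocessed
image patches under a *diversity prior* on the weight matrix, and measures
the resulting code with the evaluation stack used in studies of early
visual feature learning: Treves-Rolls selectivity and sparsity, dead-neuron
counts, reverse-correlation receptive fields with Gabor fits, and
deterministic patchwise image reconstruction.

## Model

An RBM is a bipartite Markov network over binary visibles
v ∈ {0,1}^Nv and hiddens h ∈ {0,1}^Nh with

    p(v,h) = exp(−E(v,h))/Z,   E(v,h) = −vᵀWh − hᵀb − vᵀc.

Conditionals factorize with logistic units:
p(h_j=1|v) = σ(vᵀW·j + b_j) and p(v_i=1|h) = σ(W_i·h + c_i).
Preprocessed patches are continuous in [0,1]; they enter everywhere a
binary v would, interpreted as activation probabilities. This is the
standard convention for real-valued inputs to binary RBMs and matches the
contrastive-divergence update being written in probabilities.

Training maximizes the average data log-likelihood by CD-k: the positive
phase uses the data and p(h|v); the negative phase runs k block-Gibbs
alternations (hiddens sampled binary; intermediate visibles sampled
binary) and takes the final statistics in probabilities — the
reconstruction p(v|h⁺) and p(h|v⁻). Exact log-likelihood and gradient
oracles (enumeration of the smaller layer, free-energy marginalization of
the other) are provided for instances whose smaller layer has ≤ 20 units;
they back the test suite's finite-difference and CD-expectation checks.

## Diversity prior

The prior biases weight columns (receptive fields) toward mutual
dissimilarity:

    p(W) ∝ exp(−λ Σ_{j≠k} cos²(W·j, W·k)).

MAP estimation with unit-norm columns turns the cosine into a plain dot
product, giving the per-column update term

    −2λ ( Σ_{k≠j} (W·k W·kᵀ) W·j + C (‖W·j‖−1)/‖W·j‖ · W·j ),

a repulsion of each column from every other in proportion to their overlap
plus a soft pull of column norms to 1. This term is the exact gradient of
λ[Σ_{j<k}(W·jᵀW·k)² + C Σ_j(‖W·j‖−1)²] (`diversity_potential`); note the
unordered-pair counting — the reported penalty statistic
(`squared_cosine_penalty`) counts ordered pairs, so its gradient would
carry an extra factor 2.

Two enforcement modes for the unit-norm constraint exist: the soft
C-penalty above (C defaults to 1) and hard renormalization of every column
after each update. Hard renormalization is the default: it satisfies the
constraint set exactly, and it is applied identically in *every* training
arm (including the unregularized baseline), so that λ sweeps compare arms
under a matched constraint and differences are attributable to the prior
alone. A consequence worth knowing: without the constraint, weight norms
grow freely and the squared-dot repulsion acquires a radial component that
drains column norms, which confounds λ comparisons.

Very strong priors (λ ≈ 1) produce per-update repulsion steps that can
overshoot and oscillate at practical learning rates. The training loop
therefore caps the regularizer step at `prior_step_cap` (default 0.5
weight-units) per column per update — a trust-region safeguard that
rescales, never redirects, the step. At the reference λ = 10⁻³ the cap is
never active.

## Comparison regularizers

Two activation-based regularizers from the sparse-RBM literature are
implemented for comparison; the original works define them only by
citation in this context, so the forms here are the standard ones and are
labeled reconstructions:

- **sparse_group**: weight · mean over stimuli of ‖p(h|v)‖₁/‖p(h|v)‖₂,
  the l1/l2 population-sparsity penalty (minimized by one-hot activation).
  Default weight 1.0.
- **selective**: weight · Σ_j (mean_l p(h_j|v_l) − t)², suppressing each
  unit's average activation toward a low target t (default 0.02). Default
  weight 3.0.

Both depend on the hidden biases, so their gradients are returned with
respect to W *and* b. In comparison experiments these arms train in their
native, unconstrained formulation (no column renormalization): the cited
methods place no norm constraint, and their characteristic failure mode —
units driven silent ("dead", maximal activation < 0.1 across all
stimuli) — operates partly through weight shrinkage, which renormalization
would artificially forbid. The default weights were likewise chosen so
each method operates in the regime its literature describes (the l1/l2 and
mean-activation penalties strong enough to shape the code); an order of
magnitude weaker and both collapse onto the unregularized baseline,
exhibiting neither their benefits nor their pathologies.

## Stimuli

The preprocessing pipeline follows the classical sparse-coding setup:
pseudo-whitening with R(f) = f·exp(−(f/f0)⁴) (f0 = 0.4·Nyquist = 0.2
cycles/pixel, exponent 4, both configurable), extraction of 14×14 patches
at uniformly random positions, a logistic squashing of intensities into
[0,1], and removal of patches with pixel variance below 0.1 (population
convention; a variance exactly at the threshold is kept).

Two pipeline-specific choices need stating:

- **Sigmoid statistics and gain.** Patches are z-scored against their
  source image's post-whitening mean and standard deviation (not their
  own), so flat patches map near 0.5 and are removed by the variance
  filter, while contrasty patches survive. The pipeline gain defaults to 4
  (`sigmoid_rescale` itself defaults to gain 1): whitened images are
  heavy-tailed, and var(σ(g·z)) for a standardized patch is below 1/16
  when g = 1, which would put the 0.1 variance threshold above almost
  every patch. Gain 4 saturates structured pixels so the filter does what
  it is meant to do — separate structured from flat patches.
- **Oversampling.** `prepare_patches` repeats extraction (seed-derived
  draws) until the requested number of patches survives the filter, so
  experiment sample sizes are exact.

The synthetic generator emulates the statistics that matter for this
model: a 1/f-amplitude Gaussian field as a weak background
(0.3 standard deviations by default) under a dominant population of
localized oriented elements — soft step edges and gratings of random
orientation, position, scale and frequency. The dominance of sparse
oriented structure over noise mirrors natural scenes, where contours, not
Gaussian texture, carry the contrast; with a noise-dominated field
(background weight 1, few weak edges) whitened patches are near-Gaussian
and no learning rule — diversity prior or otherwise — finds orientation-
tuned, selectively responding features. What the generator does **not**
emulate: occlusion, scale-invariant object structure, luminance/contrast
nonstationarity, and the full heavy-tailed wavelet statistics of real
scenes. Passing qualitative tests on these stimuli shows the learning
dynamics behave as described, not that the learned code matches cortex on
real images.

## Evaluation

- **Selectivity / sparsity** (Treves-Rolls): TR(r) = 1 − (Σr/N)²/(Σr²/N)
  on activation probabilities, per neuron across stimuli (selectivity) or
  per stimulus across neurons (sparsity); 0 for constant vectors,
  1 − 1/N for one-hot. An all-zero response vector is a 0/0 case and is
  defined as 0 (the unit is counted dead instead). Metrics are computed on
  the training patch set, subsampled to a 10,000-stimulus cap.
- **Dead neurons**: units with max activation probability < 0.1 (strict)
  over all stimuli.
- **Receptive fields**: RF_j = Σ_s p(h_j=1|v_s)·v_s over training patches
  (subsampled to 10,000). For Gabor fitting the ensemble pedestal
  (total activation mass × mean stimulus) is subtracted; the raw sum
  remains available.
- **Gabor fits**: Nelder-Mead least squares on the 8-parameter Gabor plus
  a constant-offset nuisance parameter (discarded on return). The offset
  matters at low frequencies: a Gabor with f ≈ 0.1 cycles/pixel on a 14 px
  patch carries substantial DC, and fitting a pure Gabor to the
  mean-subtracted field biases the recovered frequency by several percent.
  Initialization is data-driven — orientation and frequency from the FFT
  peak, center and envelope from intensity moments, four candidate carrier
  phases — followed by seeded random restarts (10 by default, stopping
  early at r² > 0.999). σ is kept in [0.3, 2·side] pixels and the center
  inside the patch by a smooth objective penalty. Parameters are
  canonicalized (A ≥ 0, θ ∈ [0,π) with phase negated on π-rotation,
  φ ∈ [−π,π)). Quality control keeps fits with r² ≥ 0.5 (configurable),
  center inside the patch and σ below the patch diagonal. Shape profiles
  are (nx, ny) = (σx·f, σy·f); the aspect-ratio orientation is
  configurable and defaults to ny/nx.
- **Reconstruction**: non-overlapping 14×14 tiling, v̂ = σ(W p(h|v) + c),
  probabilities end-to-end (deterministic); margins cropped; MSE and PSNR
  reported. Hold-out splits (8 train / 2 test by default) are seeded.

## Experiment scales

`full_scale_config()` reproduces the reference conditions: 100,000
patches from 10 images, Nv = 196, Nh = 200, CD-1, 400 epochs, batch 100,
learning rate 0.05, λ = 10⁻³. Such a run takes many hours.
`scaled_down_config()` is the desk-scale variant used by the test suite,
the examples and the acceptance script: 10,000 patches, Nh = 50,
50 epochs. The 8× shorter schedule is compensated with an 8×–10× larger
learning rate (0.5); under the unit-norm constraint CD-1 remains stable at
this step size, and the run reaches the quasi-converged regime in which
the λ ordering of the metrics is expressed. All randomness (weight
initialization, patch extraction, batch shuffling, Gibbs sampling) derives
from a single integer seed, and runs are bit-reproducible.

## Numerical choices and degenerate inputs

- Column norms are floored at 1e−12 wherever a cosine or a normalization
  divides by them.
- Exact oracles refuse instances whose smaller layer exceeds 20 units.
- Training aborts with a diagnostic if parameters become non-finite.
- A constant receptive field cannot be Gabor-fitted and raises; a fit that
  never produces a finite r² is flagged with r² = −∞.
- Zero-variance inputs: logistic rescaling returns all 0.5;
  `rf_basis_agreement` warns and returns 0.

## Known limitations

- Qualitative findings are established at desk scale (Nh = 50, 50
  epochs); magnitudes are not calibrated against any reference numbers,
  which exist only as figures. The λ orderings of the Treves-Rolls
  metrics are stochastic at this scale — the prior's effect size is
  comparable to CD-1 solution-branch variability across seeds.
- At desk scale the *selective* regularizer does not produce dead units:
  with 50 hidden units on a rich patch ensemble, every unit keeps at
  least one strongly driving stimulus, whether the suppression acts
  through the full chained gradient or directly on the biases, with or
  without the norm constraint. Silencing by mean-activation suppression
  appears to require a surplus of hidden units relative to the data's
  structure (wide hidden layers, long schedules). The sparse-group
  (l1/l2) regularizer, by contrast, silences most units at this scale.
- The Gabor fitter assumes a single oriented component; fields with two
  lobes of different orientation fit poorly (by design, such units are
  removed by quality control).
- CD-k is a biased gradient estimator; the package verifies its
  expectation against enumeration only on tiny instances.
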