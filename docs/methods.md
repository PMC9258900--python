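# Methods

## Models

**Energy-based view.**  Every model here is handled through its energy
E(s) = −log p(s) up to an additive constant.  The partition function over
q^N sequences is never computed except by explicit enumeration, which is
capped at 10⁶ sequences and used only as an oracle.

**Pairwise (Potts) and independent models.**
E_pw(s) = −Σ_{i<j} J_ij(s_i, s_j) − Σ_i h_i(s_i) − C.  Couplings are stored
once per unordered pair (i < j) with a symmetrized accessor; the constant C
is kept explicitly so that the model is a faithful order-≤2 truncation of
the general interaction expansion E(s) = Σ_{L⊆I} f_L(s_L).  Independent
models drop J; their distribution factorizes and admits exact sampling.

**Autoregressive model (`ArDCA`).**  p(s) = Π_i p(s_i | s_<i) with
p(s_i | s_<i) = softmax_a(h_i(a) + Σ_{j<i} J_ij(a, s_j)).  Likelihood and
ancestral sampling are exact.  Despite the h/J notation, the per-position
normalizers z_i(s_<i) make log p a function with interactions of every
order, so the model is *not* a Potts model — that gap is precisely what
distillation measures.  Training maximizes the reweighted log likelihood
with L2 penalties at strengths 0.01 (J) and 0.0001 (h), applied to the
unnormalized squared parameter norms, via L-BFGS with analytic gradients
from zero initialization.  The autoregressive order defaults to natural
left-to-right; an entropy-sorted order is available.

**Variational autoencoder (`SequenceVAE`).**  One hidden tanh layer on each
side; the encoder outputs a diagonal Gaussian q(z|s), the decoder a
per-position softmax; prior standard normal.  Training is full-batch
gradient descent (Adam optional) on the reweighted ELBO with weight decay
applied to weight matrices only (biases are not decayed — the usual
convention, and it keeps a decayed-to-death decoder able to represent site
biases).  All gradients are derived by hand in NumPy and are
finite-difference-checked in the test suite.  Initialization is Glorot with
a seeded generator; zero initialization is a saddle for this architecture
(with all weights zero the hidden activations vanish and the weight
gradients are identically zero), so a symmetric-broken random start is
required.  Marginal likelihoods are importance-sampling estimates with the
encoder as proposal, K = 5000 samples by default, computed in log space;
VAE energies therefore carry an `estimated` flag and record (K, seed).

## Distillation

The loss L(J, h, C) = E_{s∼D}[(E^M(s) − E_pw(s))²] is linear least squares
in the parameters, hence convex, with a null space spanned by the gauge
directions of the pairwise parameterization.  Three routes:

1. **Exact (oracle).**  Weighted least squares over a full enumeration of
   sequence space, solved by pseudo-inverse so gauge-null directions get the
   minimum-norm representative.  Used as the ground truth everywhere.
2. **Closed form for D = U.**  Under uniform weighting the minimizer is the
   order-≤2 zero-sum (Möbius) expansion: C = −mean energy, fields from
   single-site conditional means minus the grand mean, couplings from pair
   conditional means minus all lower-order terms.  The published description
   of these estimators carries a sign inconsistency in the constant's
   appearance in the field estimator; this implementation follows the form
   verified against the least-squares oracle (the package asserts the
   equivalence on enumerable models).  Estimated from a finite uniform
   sample; empty conditional cells fall back to the grand mean (zero
   coefficient), and the result is projected to the exact zero-sum gauge.
3. **Stochastic protocol for D = M.**  Prepare n_samples sequences from the
   original model with their energies; then loop: draw a batch of 10000
   with replacement from the pool, independently replace each batch element
   with a fresh uniform sequence with probability 1% (computing the original
   model's energy for the replacement on the fly, so rare symbols stay
   identifiable), take an Adam step on the batch MSE from zero
   initialization, track an exponential moving average of batch losses
   (factor 0.9, initialized to the first batch loss), and stop once the EMA
   has not reached a new minimum for 1000 steps, returning the parameters
   from the best-EMA step.  Defaults: n_samples 10⁷, Adam β = (0.9, 0.999),
   step size 10⁻³; all exposed in `ExtractionConfig`.  For independent
   models the coupling gradient is discarded.

Because the objective is convex, the stochastic route converges to the same
energies as the exact oracle on realizable problems; the tests check
agreement to 0.05 max-abs energy difference on enumerable instances.

## Gauges and oracles

`to_zero_sum_gauge` centers every coupling block along both amino-acid axes
and every field vector, folding the displaced means downward (J → h → C);
it changes no energy, is idempotent, and its output satisfies every
zero-sum constraint to ≤1e−12.  `mobius_zero_sum_expansion` computes the
orthogonal-under-uniform interaction expansion by conditional means over a
full enumeration; truncated at order 2 it coincides with uniform-weighted
extraction, and kept to full order it reconstructs E exactly.  These two
independent constructions cross-check each other in the tests.

## Synthetic data

The generator plants models with known structure: Gaussian random Potts
models (default field scale 0.5, coupling scale 0.3 — strong enough that
pairwise structure dominates single sites but enumeration-based sampling
stays well conditioned), and three-body tensors pre-centered to zero-sum
along every axis so they are *exactly* invisible to uniform-weighted
pairwise extraction, making the extraction residual analytic (the planted
part's uniform variance; the binary parity model is the sharpest case, with
residual exactly 1).  Alignments are drawn by exact categorical sampling on
enumerable models or by single-site heat-bath Gibbs (defaults: 100·N
burn-in sweeps, N sweeps thinning).  Synthetic mutational tables assign
fitness = −E(mutant) + Gaussian noise to random distinct single
substitutions, so rank agreement with the generating model is perfect at
zero noise.

What the synthetic data does **not** emulate: phylogenetic correlation
between sequences, alignment-depth/gap-pattern artifacts of real MSAs, and
experimentally realistic (non-Gaussian, measurement-specific) fitness
noise.  Passing tests therefore demonstrate the correctness of the
machinery and the identifiability properties of the method, not its
performance on any real protein family.

## Evaluation

Energy error is the RMSE divided by the range of the original energies on
the evaluation set; reports stratify the test set into the 10% of sequences
farthest from the training set (minimum normalized Hamming distance,
nearest-integer rounding, ties to earlier index) versus the remaining 90%,
plus the mutational sequences.  Mutational-effect prediction correlates
−E with fitness (so good models score positive).  Contact scores follow the
standard DCA recipe: zero-sum gauge, Frobenius norm per coupling block
excluding the gap symbol when the alphabet has one, average product
correction, minimum sequence separation 5 — each step configurable.
Distance diagnostics bin by the unique observed minimum distances without
smoothing, since distances are discrete for domain-scale N.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: enumerable models
(q^N ≤ 3⁶), alignments of 500–2000 sequences, extraction pools of 10⁵
samples with Adam step size 0.01, and VAE importance sampling at K = 500
for bulk energies (K = 5000 where a single estimate is checked against
quadrature).  These sizes were chosen so every check closes the loop
against an exact oracle; the library defaults remain the full-scale
protocol values.  Degenerate cases are handled explicitly: zero-range
energy vectors make NRMSE undefined (error, or recorded as missing inside
reports), constant vectors make rank correlations undefined (error),
empty conditional cells in the closed-form estimators fall back to the
grand mean, and all stochastic estimators are deterministic given their
seed.

## Known limitations

- Extraction beyond order 2 (higher-order or sparse interaction recovery)
  is out of scope.
- `PairwiseModel.sample` enumerates; large-N Potts sampling goes through
  the Gibbs sampler, whose mixing is the user's responsibility.
- The VAE is deliberately the one-hidden-layer architecture; deeper
  variants, sparse priors and temperature scaling are not implemented.
- The exact least-squares route scales as (samples × parameters) memory and
  is an oracle for toy sizes, not a production solver.
- Contact evaluation consumes a precomputed contact list; no structure
  parsing is included.
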