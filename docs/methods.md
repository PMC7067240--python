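# Methods

## Model and procedure

The pipeline couples three learned components.

**SMILES VAE.** Strings are tokenized at the character level (Cl and Br
merged into single tokens) and one-hot encoded into fixed-length L×A
matrices, pad token last.  The reference model is a compact feed-forward
network: one ReLU hidden layer to the mean and log-variance of a diagonal
Gaussian q(z|m), and one ReLU hidden layer from z to independent per-position
categorical logits.  Training maximizes the plain ELBO (per-position
cross-entropy plus analytic KL to N(0, I), KL weight 1) with Adam.  Decoding
samples every position at temperature 1 and truncates at the first pad
token, so a latent point induces a distribution over strings; the
"most probable decoding" is the modal string among n sampled attempts, ties
broken lexicographically.  The surrounding pipeline touches the VAE only
through encode / decode-attempts, so the architecture can be swapped without
disturbing anything else.  The per-position independence of the decoder is
the model's main simplification: it caps reconstruction sharpness relative
to an autoregressive decoder, which is why desk-scale realism percentages sit
near 50% rather than the high values a sequence decoder reaches at scale.

**Feasibility constraint.** A latent point is labelled feasible when
strictly more than 20% of its decode attempts are *realistic* — valid under
RDKit sanitization and longer than 5 characters, a cutoff that excludes
degenerate decodings like methane.  The classifier is a 2×100 ReLU network
with logistic output and a mean-field Gaussian posterior over all weights,
trained by stochastic variational inference with the local
reparameterization trick; the predictive probability averages the logistic
output over posterior weight samples frozen at the end of training (so
predictions are deterministic).  The Bayesian treatment is load-bearing:
a point-estimate network extrapolates its decision boundary confidently into
regions it has never seen, whereas here the logit variance grows with
distance from the data and the averaged probability decays toward chance in
typical far-away directions.  One caveat is intrinsic to any logistic
network: along the learned discriminant's positive direction, the logit mean
and standard deviation both scale linearly with distance, so confidence does
not decay there.  The search is box-bounded, so this beyond-box behaviour
never enters the optimization.

**Constrained BO.** The engine minimizes the negated, standardized score
under Pr(C(z)) ≥ 1 − δ.  The objective surrogate is an RBF-kernel GP (scalar
lengthscale, signal and noise variances, maximum marginal likelihood by
multi-start L-BFGS with analytic gradients), with an optional
inducing-point mode (deterministic training conditional) that reproduces the
exact posterior when the inducing set equals the training set.  Acquisition
is EIC(z) = Pr(C(z))·EI(z) in the independent-product form.  Kriging-
Believer batch proposal conditions the GP on each pick's posterior mean via
a rank-one Cholesky update; hyperparameters are re-optimized once per outer
iteration, not within a batch.

## Incumbent rule

The incumbent is the minimum GP posterior mean over observed points
satisfying the probabilistic constraint.  Because evaluations that decode to
non-realistic molecules are excluded from the surrogate data, *every*
surrogate input is a successfully evaluated (feasible) point.  When label
noise caps the classifier's calibrated probability ceiling below 1 − δ, a
rule that insists on Pr ≥ 1 − δ would abandon the objective permanently and
re-propose the argmax-probability point forever.  The engine therefore falls
back to the minimum posterior mean over all observed feasible points
whenever the probabilistic threshold is unattained among them; the
objective-blind feasibility search is reserved for the situation it was
designed for — no feasible point located yet.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| latent_dim | 8 (desk) / 56 (full scale) | latent dimensionality d |
| realistic length cutoff | 5 (strict >) | characters; realism predicate |
| label threshold | 0.20 (strict >) | fraction of realistic decode attempts |
| n_decode_attempts | 100 (labelling), 500 (diagnostics) | decode attempts per latent point |
| δ | 0.05 | confidence demand of the probabilistic constraint |
| constraint net | 2×100 ReLU, minibatch 1000, 5 epochs, lr 5e-4 | full-scale training settings |
| desk constraint config | minibatch 128, 300 epochs, lr 1e-3, kl_weight 0.1 | small-corpus settings |
| BO schedule | 20 iterations × batch 50 (full) | desk runs shrink both |
| acquisition search | 256 uniform candidates + L-BFGS polish of top 3, plus jittered best-observed anchors | per batch position, seeded |
| property regressor | 512-bit radius-2 Morgan fingerprints, 2×50 ReLU ensemble, 25 epochs, batch 500, lr 0.01 | learned-objective mode |

δ is user-specified.  Note its interaction with label noise: with flip rate
ε, the Bayes-optimal in-region probability is 1 − ε, so demanding
1 − δ > 1 − ε is unattainable for a calibrated classifier; the incumbent
fallback above keeps the engine live in that regime.

`kl_weight` tempers the variational posterior (KL term scaled by
kl_weight/N).  At desk scale a (100,100) network has orders of magnitude
more weights than there are training points, and untempered mean-field VI is
severely underconfident (predictions near 0.5 even at the class centroid);
kl_weight = 0.1 restores calibration close to the Bayes-optimal ceiling
while preserving the uncertainty-driven far-field decay.  The full-scale
default keeps kl_weight = 1.

## Synthetic data

The toy corpus is drawn from a small stochastic grammar: C/N/O chains with
single-atom branches on carbon only (so valence limits cannot be violated)
and 5–8-membered carbocycles, plus a 5% admixture of deliberately short
strings (methane, ethanol, ...).  Every string is re-checked with RDKit at
generation.  The grammar guarantees support on both sides of the realism
cutoff and non-trivial ring penalties, but it does not emulate real chemical
libraries: no aromaticity, charges, stereochemistry, fused rings, or
drug-like functional groups.  Tests passing on this corpus demonstrate the
machinery — encoding, labelling, constrained search — not chemical coverage;
scores and percentile claims on the toy corpus say nothing about
library-scale chemistry.

The constrained Branin-Hoo family provides ground truth the molecular
problem lacks: a known feasible region (disk or half-plane, constructed to
exclude at least one of the three global minimizers) and a brute-force
constrained optimum computed on a 2001×2001 grid (sub-0.01 resolution,
seconds of compute).  The feasibility classifier is trained on uniformly
sampled points whose true labels are flipped with probability 0.1,
emulating the noisy labelling the decode-attempt rule produces.

## Numerical choices

- **Log-scale observations on Branin.**  The function spans three orders of
  magnitude over its domain; after standardization the basin bottom is a
  ~4×10⁻³ feature that a stationary GP's marginal-likelihood fit smooths
  away, stalling refinement around 10% above the optimum.  The validation
  experiment therefore models −log(1+f); the transform is monotone, so the
  constrained minimizer is unchanged.  Median recovery across seeds is then
  within 0.5% of the grid optimum.
- **Adaptive jitter.**  Cholesky factorizations start at 1e-12×scale jitter
  and escalate ×100 on failure; the inducing-point mode matches the exact
  posterior to ~1e-6 at the full-inducing limit.
- **Tie-breaks.**  Modal decoding breaks ties lexicographically
  (deterministic, seed-independent).  Coincident Kriging-Believer picks —
  possible in feasibility-only mode, where hallucination does not change the
  acquisition — are displaced by a small seeded Gaussian jitter.
- **Degenerate inputs.**  Empty corpora, single-class constraint data,
  collapsed latent boxes, constant property targets, sub-2-point GP data and
  non-finite latents all raise typed errors at the module boundary;
  non-realistic decodings during optimization are recorded outcomes, never
  errors.
- **Standardization.**  Composite objective components are standardized by
  training-corpus mean/std before combination (config switch for raw
  combination); objective values are standardized by the initial design
  before GP fitting; property-model targets by the training split.
- **Noise interpretation.**  "x% latent noise" is multiplicative
  (per-coordinate std = fraction × |value|), with an additive-scaled
  alternative behind a flag.

## Problem sizes used in tests

The bundled suite trains the toy VAE on 1000 grammar strings (d=8, 30
epochs, ~1 s), labels constraint data with 25 decode attempts per point,
runs the Branin validation as 10 seeded runs of 15 iterations × batch 2
against the grid oracle, the dead-zone comparison with 50 points × 100
attempts per set, and the bookkeeping check as a full 20×50 schedule over a
stub decoder.  These sizes were chosen so the whole suite runs in minutes on
one CPU while every claim is still computed, not asserted.

## Known limitations

- The constraint is trained once and frozen; points observed during BO do
  not update it.  A run whose proposals concentrate in a
  confident-but-wrong pocket of the classifier can waste its budget there
  (observed occasionally on the noisy Branin fixture), since infeasible
  evaluations neither update the GP nor the constraint.
- The feed-forward decoder's positional independence limits attainable
  validity; conclusions about absolute validity rates do not transfer to
  autoregressive decoders.
- The GP uses a single shared lengthscale; strongly anisotropic objectives
  may warrant ARD.
- The bundled structural-alert sets are small synthetic placeholders for
  curated collections (PAINS etc.), sufficient to exercise the screening
  machinery but not a medicinal-chemistry filter.
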