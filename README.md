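# molbo — constrained Bayesian optimization over a SMILES VAE latent space

Generative molecular design with a character-level SMILES variational
autoencoder runs into a well-known pathology: Bayesian optimization over the
continuous latent space happily proposes points far from the region the VAE
was trained on, and those points decode to invalid or degenerate strings
(most infamously, endless methane).  `molbo` implements the constrained
formulation of that search for cheminformatics and ML-for-molecules
practitioners: a learned probabilistic feasibility constraint keeps the
acquisition inside the decodable region, so the optimizer spends its budget
on molecules that actually exist.

## The method

Molecules m are encoded as one-hot matrices of their SMILES characters and
mapped to latent vectors z by a VAE (encoder q_φ(z|m), probabilistic decoder
p_θ(m|z), standard-normal prior, ELBO training).  The search solves

    min f(z)   subject to   Pr(C(z)) ≥ 1 − δ,

where f is the negated molecular score and C(z) is the Boolean event that z
decodes to *realistic* molecules (valid SMILES longer than 5 characters) in
more than 20% of decode attempts.  Pr(C(z)) is a Bayesian neural network
classifier (2×100 ReLU, logistic output, mean-field variational posterior)
trained once on positives (encoded training molecules) and negatives
(uniform samples over the latent bounding box).

Acquisition is expected improvement with constraints,

    EIC(z) = Pr(C(z)) · EI(z),   EI(z) = E[max(0, η − f(z))],

with the incumbent η the minimum GP posterior mean over constraint-feasible
observed points; until a feasible point is located the engine maximizes
Pr(C(z)) alone.  Batches are proposed with Kriging-Believer: each pick's
outcome is hallucinated as the GP posterior mean before the next pick.

Objectives: penalized logP (logP − SA − ring-penalty, components
standardized over the training corpus), penalized QED, raw QED, or a learned
property surrogate (Morgan-fingerprint Bayesian regressor, e.g. for power
conversion efficiency).

## Worked example

```bash
molbo fixtures  --n 120 --seed 3 --out corpus.smi
molbo train-vae --corpus corpus.smi --epochs 15 --out vae.ckpt
molbo diagnose  --vae vae.ckpt --corpus corpus.smi --n-points 10 --n-attempts 50
```

Training reports the held-out negative ELBO falling from 42.49 to 24.24 —
the reconstruction-plus-KL objective is improving.  The diagnostic then
decodes 10 encoded training points, the same points with increasing latent
noise, and uniform-random latent points, 50 attempts each:

```
"train+big-noise":  { "pct_valid": 29.0, "pct_methane": 1.4, "pct_realistic": 9.4 }
"uniform-random":   { "pct_valid": 25.4, "pct_methane": 1.6, "pct_realistic": 7.2 }
```

Realism falls as points move away from the training data — the dead-zone
effect the constraint is built to avoid.  `molbo label`, `molbo
train-constraint` and `molbo optimize` then build the labelled latent
dataset, fit the feasibility classifier, and run the constrained search,
writing a per-point history CSV and a scored SMILES list.

The same workflow is available as library calls (`molbo.train_vae`,
`molbo.build_constraint_dataset`, `molbo.run_bo`, ...), which is the more
convenient route for experiments.

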