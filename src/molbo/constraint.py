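"""The learned feasibility constraint Pr(C(z)).

A latent point satisfies the Boolean constraint C(z) when it decodes to
realistic molecules in more than a threshold fraction (default 20%, strict)
of its decode attempts.  Labelled points — positives from encodings of the
training corpus, negatives from uniform samples over a latent bounding box —
train an approximate-Bayesian binary classifier whose predictive probability
defines the probabilistic feasible region {z : Pr(C(z)) >= 1 − delta}.

The classifier is a 2x100 ReLU network with logistic output and a
mean-field Gaussian posterior over its weights (stochastic variational
inference); the predictive probability averages the logistic output over a
configurable number of posterior weight samples.  Far from the training data
the sampled logits disagree and the averaged probability decays toward
chance — the property that keeps the acquisition out of latent dead zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vae import LatentPoint, VAEModel

_PROB_EPS = 1e-6  # predictions are clipped into (eps, 1-eps): never saturated

DEFAULT_LABEL_THRESHOLD = 0.20
DEFAULT_DELTA = 0.05


class ConstraintError(ValueError):
    pass


def label_latent_point(
    model: VAEModel,
    z: LatentPoint,
    n_attempts: int = 100,
    threshold: float = DEFAULT_LABEL_THRESHOLD,
    seed: int = 0,
) -> int:
    """1 iff strictly more than ``threshold`` of decode attempts are realistic."""
    from .smiles_codec import is_realistic

    if n_attempts < 1:
        raise ConstraintError("n_attempts must be >= 1")
    if not 0.0 < threshold < 1.0:
        raise ConstraintError("threshold must lie in (0, 1)")
    attempts = model.decode_attempts(z, n_attempts, seed)
    frac = sum(is_realistic(s) for s in attempts) / n_attempts
    return int(frac > threshold)


@dataclass
class ConstraintDataset:
    """Labelled latent points with per-point provenance."""

    points: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) in {0, 1}
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.ndim != 2 or len(self.labels) != len(self.points):
            raise ConstraintError("points must be (n, d) with matching labels")
        if not np.isin(self.labels, (0, 1)).all():
            raise ConstraintError("labels must be binary")
        if not self.provenance:
            self.provenance = ["unspecified"] * len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.points, columns=[f"z{i}" for i in range(self.points.shape[1])]
        )
        df["label"] = self.labels
        df["provenance"] = self.provenance
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConstraintDataset":
        zcols = [c for c in df.columns if c.startswith("z")]
        return cls(
            points=df[zcols].to_numpy(float),
            labels=df["label"].to_numpy(int),
            provenance=list(df.get("provenance", ["unspecified"] * len(df))),
        )


def latent_bounding_box(
    encodings: np.ndarray, expand_fraction: float = 0.10
) -> np.ndarray:
    """Axis-aligned bounding box of encoded data, expanded per side, (d, 2)."""
    lo = encodings.min(axis=0)
    hi = encodings.max(axis=0)
    span = hi - lo
    return np.stack([lo - expand_fraction * span, hi + expand_fraction * span], axis=1)


def build_constraint_dataset(
    model: VAEModel,
    corpus: list[str],
    n_negative: int,
    latent_bounds: np.ndarray | None = None,
    n_attempts: int = 100,
    threshold: float = DEFAULT_LABEL_THRESHOLD,
    seed: int = 0,
    balance: bool = True,
) -> ConstraintDataset:
    """Label corpus encodings (positives) and uniform box samples (negatives).

    Corpus encodings failing the labelling rule are dropped from the positive
    class, and uniform samples passing it are dropped from the negative class
    (each class keeps only the label the sampling scheme targets, mirroring
    how the full-scale constraint data were collected).  By default the larger
    class is subsampled to match the smaller.
    """
    rng = np.random.default_rng(seed)
    enc = np.stack([model.encode(s).z for s in corpus])
    if latent_bounds is None:
        latent_bounds = latent_bounding_box(enc)
    latent_bounds = np.asarray(latent_bounds, dtype=float)
    if latent_bounds.shape != (model.latent_dim, 2) or not np.isfinite(latent_bounds).all():
        raise ConstraintError("latent_bounds must be a finite (d, 2) box")

    positives = []
    for i, z in enumerate(enc):
        lab = label_latent_point(
            model, LatentPoint(z), n_attempts, threshold, seed=int(seed + 1000 + i)
        )
        if lab == 1:
            positives.append(z)

    negatives = []
    widths = latent_bounds[:, 1] - latent_bounds[:, 0]
    samples = latent_bounds[:, 0] + rng.random((n_negative, model.latent_dim)) * widths
    for i, z in enumerate(samples):
        lab = label_latent_point(
            model, LatentPoint(z), n_attempts, threshold, seed=int(seed + 500000 + i)
        )
        if lab == 0:
            negatives.append(z)

    if not positives or not negatives:
        raise ConstraintError(
            "a class came back empty after labelling "
            f"(positives={len(positives)}, negatives={len(negatives)}); "
            "revise latent_bounds or the labelling threshold"
        )
    if balance:
        k = min(len(positives), len(negatives))
        positives = [positives[i] for i in rng.choice(len(positives), k, replace=False)]
        negatives = [negatives[i] for i in rng.choice(len(negatives), k, replace=False)]

    points = np.vstack([positives, negatives])
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    prov = ["encoded-training-data"] * len(positives) + [
        "uniform-latent-sample"
    ] * len(negatives)
    return ConstraintDataset(points=points, labels=labels, provenance=prov)


@dataclass
class ConstraintConfig:
    """Classifier settings; defaults follow the full-scale pipeline
    (2 hidden layers x 100 ReLU units, logistic output, minibatch 1000,
    5 epochs, learning rate 0.0005).  ``n_posterior_samples`` controls how
    many posterior weight draws the predictive probability averages over."""

    hidden_layers: tuple[int, int] = (100, 100)
    batch_size: int = 1000
    epochs: int = 5
    learning_rate: float = 0.0005
    n_posterior_samples: int = 50
    kl_weight: float = 1.0
    delta: float = DEFAULT_DELTA


def desk_scale_config(**overrides) -> ConstraintConfig:
    """Classifier settings tuned for small corpora: more epochs and smaller
    minibatches than the full-scale defaults, which assume ~2e5 points."""
    base = dict(batch_size=128, epochs=300, learning_rate=0.001, kl_weight=0.1)
    base.update(overrides)
    return ConstraintConfig(**base)


@dataclass
class ConstraintModel:
    """Variational-BNN feasibility classifier exposing Pr(C(z))."""

    config: ConstraintConfig
    network: "BayesianMLPClassifier"
    latent_dim: int

    @property
    def delta(self) -> float:
        return self.config.delta

    def predict_probability(self, Z: np.ndarray) -> np.ndarray:
        """Pr(C(z)) for each row of Z, strictly inside (0, 1)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.latent_dim:
            raise ConstraintError(
                f"latent dimension mismatch: got {Z.shape[1]}, expected {self.latent_dim}"
            )
        probs = self.network.predict_proba(Z)[:, 1]
        return np.clip(probs, _PROB_EPS, 1.0 - _PROB_EPS)


def train_constraint_classifier(
    data: ConstraintDataset, config: ConstraintConfig | None = None, seed: int = 0
) -> ConstraintModel:
    """Fit the variational-BNN feasibility classifier; deterministic under
    seed (the predictive averages over posterior weight samples frozen at
    the end of training)."""
    from .bnn import BayesianMLPClassifier

    config = config or ConstraintConfig()
    classes = np.unique(data.labels)
    if len(classes) < 2:
        raise ConstraintError("constraint training data must contain both classes")

    net = BayesianMLPClassifier(
        hidden_layers=config.hidden_layers,
        epochs=config.epochs,
        batch_size=min(config.batch_size, len(data.labels)),
        learning_rate=config.learning_rate,
        kl_weight=config.kl_weight,
        n_posterior_samples=config.n_posterior_samples,
        seed=int(seed % (2**31 - 1)),
    ).fit(data.points, data.labels)
    return ConstraintModel(
        config=config, network=net, latent_dim=data.points.shape[1]
    )


def constraint_probability(cm: ConstraintModel, z: LatentPoint | np.ndarray) -> float:
    """Pr(C(z)) for a single latent point."""
    vec = z.z if isinstance(z, LatentPoint) else np.asarray(z, dtype=float)
    return float(cm.predict_probability(vec[None, :])[0])
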