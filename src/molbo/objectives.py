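"""Molecular scoring functions and the noisy latent-space evaluation protocol.

Three objectives are supported, all "larger is better":

* ``composite_logp``  — logP − SA − ring-penalty, each component standardized
  by its training-corpus mean/std before combination (the "penalised logP"
  convention of this literature); a raw, unstandardized combination is
  available by passing unit stats.
* ``composite_qed``   — QED − SA − ring-penalty, same standardization.
* ``qed``             — raw QED in [0, 1].
* ``learned``         — predictive mean of a fingerprint-based property
  regressor (e.g. a power-conversion-efficiency surrogate).

Evaluating an objective at a *latent point* is noisy: the point is decoded
stochastically many times, the modal string is retained, and only a realistic
retained molecule is scored — a non-realistic one yields an *infeasible*
outcome that is recorded, never imputed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, QED, RDConfig
from rdkit.Chem import rdFingerprintGenerator

from .smiles_codec import Molecule
from .vae import LatentPoint, VAEModel

# Ertl-Schuffenhauer synthetic-accessibility scorer shipped with RDKit
sys.path.append(str(Path(RDConfig.RDContribDir) / "SA_Score"))
import sascorer  # noqa: E402


class ObjectiveError(ValueError):
    pass


def _mol(m: Molecule) -> Chem.Mol:
    if not m.valid:
        raise ObjectiveError(f"cannot score invalid molecule {m.smiles!r}")
    return Chem.MolFromSmiles(m.smiles)


def logp(m: Molecule) -> float:
    """Crippen estimate of the water-octanol partition coefficient."""
    return float(Crippen.MolLogP(_mol(m)))


def qed(m: Molecule) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    return float(QED.qed(_mol(m)))


def sa_score(m: Molecule) -> float:
    """Ertl-Schuffenhauer synthetic accessibility, in [1, 10] (1 = easy)."""
    return float(sascorer.calculateScore(_mol(m)))


def ring_penalty(m: Molecule) -> float:
    """max(0, largest ring size − 6); penalizes macrocycles."""
    mol = _mol(m)  # bound: RingInfo must not outlive its molecule
    rings = mol.GetRingInfo().AtomRings()
    largest = max((len(r) for r in rings), default=0)
    return float(max(0, largest - 6))


@dataclass
class ComponentStats:
    """Per-component normalization statistics (training-corpus mean/std)."""

    mean: dict[str, float]
    std: dict[str, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std.values()):
            raise ObjectiveError("component std must be strictly positive")

    @classmethod
    def unit(cls, components: tuple[str, ...]) -> "ComponentStats":
        return cls(mean={c: 0.0 for c in components}, std={c: 1.0 for c in components})


_COMPONENT_FNS = {"logp": logp, "qed": qed, "sa": sa_score, "ring": ring_penalty}

_COMPOSITES = {
    "composite_logp": ("logp", "sa", "ring"),
    "composite_qed": ("qed", "sa", "ring"),
}


def compute_component_stats(corpus: list[str], components: tuple[str, ...]) -> ComponentStats:
    """Mean/std of each named component over the (valid) corpus molecules."""
    vals: dict[str, list[float]] = {c: [] for c in components}
    for s in corpus:
        m = Molecule.from_smiles(s)
        if not m.valid:
            continue
        for c in components:
            vals[c].append(_COMPONENT_FNS[c](m))
    mean = {c: float(np.mean(v)) for c, v in vals.items()}
    std = {c: max(float(np.std(v)), 1e-8) for c, v in vals.items()}
    return ComponentStats(mean=mean, std=std)


@dataclass
class ObjectiveSpec:
    """Which score is optimized and how it is evaluated in latent space."""

    name: str = "composite_logp"
    component_stats: ComponentStats | None = None
    n_decode_attempts: int = 100
    property_model: "PropertyModel | None" = None

    def __post_init__(self) -> None:
        if self.name not in ("composite_logp", "composite_qed", "qed", "learned"):
            raise ObjectiveError(f"unknown objective {self.name!r}")
        if self.name in _COMPOSITES and self.component_stats is None:
            self.component_stats = ComponentStats.unit(_COMPOSITES[self.name])
        if self.name == "learned" and self.property_model is None:
            raise ObjectiveError("learned objective requires a property model")


def score(spec: ObjectiveSpec, m: Molecule) -> float:
    """Score a molecule under the objective; larger is better."""
    if spec.name == "qed":
        return qed(m)
    if spec.name == "learned":
        return float(spec.property_model.predict([m])[0][0])
    components = _COMPOSITES[spec.name]
    stats = spec.component_stats
    first, *penalties = components
    total = (_COMPONENT_FNS[first](m) - stats.mean[first]) / stats.std[first]
    for c in penalties:
        total -= (_COMPONENT_FNS[c](m) - stats.mean[c]) / stats.std[c]
    return float(total)


@dataclass(frozen=True)
class LatentEvaluation:
    """Outcome of evaluating an objective at one latent point."""

    molecule: Molecule
    value: float | None  # None = infeasible (retained string not realistic)

    @property
    def feasible(self) -> bool:
        return self.value is not None


def evaluate_latent(
    spec: ObjectiveSpec, model: VAEModel, z: LatentPoint, seed: int
) -> LatentEvaluation:
    """Decode z via the modal-string protocol and score the result.

    A retained string that is not realistic produces an infeasible outcome
    (value ``None``); it is recorded but never scored or imputed.
    """
    mol = model.most_probable_decoding(z, spec.n_decode_attempts, seed)
    if not mol.realistic:
        return LatentEvaluation(molecule=mol, value=None)
    return LatentEvaluation(molecule=mol, value=score(spec, mol))


# --- learned property objective (fingerprints + ensemble regressor) --------


def morgan_fingerprint(m: Molecule, n_bits: int = 512, radius: int = 2) -> np.ndarray:
    """Morgan circular fingerprint as a {0,1} vector of length ``n_bits``."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(_mol(m))
    arr = np.zeros(n_bits, dtype=np.int8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


@dataclass
class PropertyModelConfig:
    """Fingerprint featurizer and regressor settings.

    Defaults follow the property-surrogate convention this pipeline models:
    512-bit radius-2 Morgan fingerprints into a 2x50 ReLU network trained for
    25 epochs with Adam (lr 0.01, minibatch 500), with an ensemble standing
    in for the posterior over weights.
    """

    n_bits: int = 512
    radius: int = 2
    hidden_layers: tuple[int, int] = (50, 50)
    epochs: int = 25
    batch_size: int = 500
    learning_rate: float = 0.01
    n_ensemble: int = 5
    test_fraction: float = 0.1


@dataclass
class PropertyModel:
    """Ensemble regressor over fingerprints with predictive mean/variance."""

    config: PropertyModelConfig
    members: list
    target_mean: float
    target_std: float
    train_rmse: float
    test_rmse: float

    def featurize(self, mols: list[Molecule]) -> np.ndarray:
        return np.stack(
            [morgan_fingerprint(m, self.config.n_bits, self.config.radius) for m in mols]
        ).astype(float)

    def predict(self, mols: list[Molecule]) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and variance per molecule, on the original scale."""
        X = self.featurize(mols)
        preds = np.stack([m.predict(X) for m in self.members])
        mean = preds.mean(axis=0) * self.target_std + self.target_mean
        var = preds.var(axis=0) * self.target_std**2
        return mean, var


def train_property_model(
    pairs: list[tuple[str, float]], config: PropertyModelConfig, seed: int
) -> PropertyModel:
    """Fit the ensemble property regressor on (SMILES, target) pairs.

    Targets are standardized by the training split's empirical mean/variance;
    train/test RMSE are reported on the original target scale.
    """
    from sklearn.neural_network import MLPRegressor

    mols = [Molecule.from_smiles(s) for s, _ in pairs]
    bad = [m.smiles for m in mols if not m.valid]
    if bad:
        raise ObjectiveError(f"invalid SMILES in property pairs: {bad[:10]}")
    y = np.array([t for _, t in pairs], dtype=float)
    if not np.isfinite(y).all():
        raise ObjectiveError("property targets must be finite")

    rng = np.random.default_rng(seed)
    n = len(pairs)
    n_test = max(1, int(round(config.test_fraction * n)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    tmp = PropertyModel(
        config=config, members=[], target_mean=0.0, target_std=1.0,
        train_rmse=np.nan, test_rmse=np.nan,
    )
    X = tmp.featurize(mols)
    y_mean = float(y[train_idx].mean())
    y_std = float(y[train_idx].std())
    if y_std <= 0:
        raise ObjectiveError("degenerate target variance")
    y_norm = (y - y_mean) / y_std

    members = []
    for k in range(config.n_ensemble):
        reg = MLPRegressor(
            hidden_layer_sizes=config.hidden_layers,
            activation="relu",
            solver="adam",
            learning_rate_init=config.learning_rate,
            batch_size=min(config.batch_size, len(train_idx)),
            max_iter=config.epochs,
            random_state=int(seed % (2**31 - 1) + k),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg.fit(X[train_idx], y_norm[train_idx])
        members.append(reg)

    model = PropertyModel(
        config=config, members=members,
        target_mean=y_mean, target_std=y_std,
        train_rmse=np.nan, test_rmse=np.nan,
    )
    for name, idx in (("train_rmse", train_idx), ("test_rmse", test_idx)):
        pred, _ = model.predict([mols[i] for i in idx])
        setattr(model, name, float(np.sqrt(np.mean((pred - y[idx]) ** 2))))
    return model
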