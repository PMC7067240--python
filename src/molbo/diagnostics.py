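"""Dead-zone diagnostics, decode statistics and the drug-likeness screen.

The dead-zone experiment perturbs encoded training points with multiplicative
Gaussian noise at increasing levels (presets 1%, 10%, 50%), decodes every
point many times, and reports the percentage of decodings that are valid,
that are methane (``"C"``, the degenerate decoding the decoder over-produces
far from the data), and that are realistic.  The drug-likeness screen applies
named SMARTS structural-alert sets plus a 150-500 Da average-molecular-weight
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .smiles_codec import Molecule, is_realistic, is_valid
from .vae import LatentPoint

NOISE_PRESETS = {"very-small": 0.01, "small": 0.10, "big": 0.50}

MW_WINDOW = (150.0, 500.0)


class DiagnosticsError(ValueError):
    pass


def perturb_latents(
    points: np.ndarray, noise_fraction: float, seed: int, additive_scale: bool = False
) -> np.ndarray:
    """Add zero-mean Gaussian noise per coordinate.

    By default the noise std is ``noise_fraction × |coordinate|``
    (multiplicative reading of "x% noise"); with ``additive_scale`` the std is
    ``noise_fraction × per-dimension std`` of the point set instead.
    """
    if noise_fraction < 0:
        raise DiagnosticsError("noise_fraction must be >= 0")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if noise_fraction == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    if additive_scale:
        scale = noise_fraction * points.std(axis=0, keepdims=True)
    else:
        scale = noise_fraction * np.abs(points)
    return points + rng.standard_normal(points.shape) * scale


@dataclass(frozen=True)
class DecodeStats:
    """Decode-attempt percentages averaged over a set of latent points."""

    n_points: int
    n_attempts: int
    pct_valid: float
    pct_methane: float
    pct_realistic: float

    def __post_init__(self) -> None:
        if not (
            0.0 <= self.pct_realistic <= self.pct_valid <= 100.0
            and self.pct_methane <= self.pct_valid
        ):
            raise DiagnosticsError("inconsistent decode percentages")


def decode_statistics(
    model, points: np.ndarray, n_attempts: int, seed: int
) -> DecodeStats:
    """Per-point percentages of valid / methane / realistic decodings,
    averaged over the point set."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise DiagnosticsError("empty point set")
    if n_attempts < 1:
        raise DiagnosticsError("n_attempts must be >= 1")
    pv, pm, pr = [], [], []
    cache: dict[str, tuple[bool, bool]] = {}
    for i, z in enumerate(points):
        attempts = model.decode_attempts(
            LatentPoint(z), n_attempts, seed=int(seed + i)
        )
        flags = []
        for s in attempts:
            if s not in cache:
                v = is_valid(s)
                cache[s] = (v, v and is_realistic(s))
            flags.append(cache[s])
        pv.append(100.0 * sum(f[0] for f in flags) / n_attempts)
        pm.append(100.0 * sum(s == "C" for s in attempts) / n_attempts)
        pr.append(100.0 * sum(f[1] for f in flags) / n_attempts)
    return DecodeStats(
        n_points=len(points),
        n_attempts=n_attempts,
        pct_valid=float(np.mean(pv)),
        pct_methane=float(np.mean(pm)),
        pct_realistic=float(np.mean(pr)),
    )


# --- structural-alert screen ----------------------------------------------


def load_alert_sets(directory: str | Path | None = None) -> dict[str, list[tuple]]:
    """Load named SMARTS alert sets.

    Each file is one set: lines of ``SMARTS<tab>description``, '#' comments
    ignored.  Without a directory the bundled *synthetic* placeholder sets
    are used (8 small generic-reactivity pattern lists standing in for
    curated alert collections, which are not redistributed here).
    """
    if directory is None:
        directory = resources.files("molbo") / "data" / "alerts_synthetic"
    directory = Path(str(directory))
    sets: dict[str, list[tuple]] = {}
    for path in sorted(directory.glob("*.txt")):
        patterns = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smarts, _, desc = line.partition("\t")
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise DiagnosticsError(
                    f"malformed SMARTS {smarts!r} in alert set {path.name}"
                )
            patterns.append((smarts, desc, patt))
        sets[path.stem] = patterns
    if not sets:
        raise DiagnosticsError(f"no alert sets found in {directory}")
    return sets


@dataclass(frozen=True)
class AlertScreenResult:
    """Per-set pass/fail plus the molecular-weight window check."""

    set_passed: dict[str, bool]
    molecular_weight: float
    overall_druglike: bool


def apply_alert_screen(
    m: Molecule, alert_sets: dict[str, list[tuple]] | None = None
) -> AlertScreenResult:
    """A set fails iff any of its SMARTS patterns matches; drug-like requires
    all sets passed and average MW within 150-500 Da."""
    if not m.valid:
        raise DiagnosticsError(f"cannot screen invalid molecule {m.smiles!r}")
    alert_sets = alert_sets if alert_sets is not None else load_alert_sets()
    mol = Chem.MolFromSmiles(m.smiles)
    passed = {
        name: not any(mol.HasSubstructMatch(p) for _, _, p in patterns)
        for name, patterns in alert_sets.items()
    }
    mw = float(Descriptors.MolWt(mol))
    overall = all(passed.values()) and MW_WINDOW[0] <= mw <= MW_WINDOW[1]
    return AlertScreenResult(
        set_passed=passed, molecular_weight=mw, overall_druglike=overall
    )


# --- run summary -----------------------------------------------------------


def summarize_run(
    history,
    training_corpus: list[str],
    training_scores: np.ndarray | None = None,
    alert_sets: dict | None = None,
) -> dict:
    """Grade a BO run: validity/realism rates, unique-novel counts, the
    alert-screen pass rate, and score percentiles of the new molecules
    against the training-score distribution (empirical CDF × 100)."""
    if not history.iterations:
        raise DiagnosticsError("empty history")
    mols = [m for it in history.iterations for m in it.molecules]
    values = [v for it in history.iterations for v in it.values]
    n = len(mols)
    valid = [m for m in mols if isinstance(m, Molecule) and m.valid]
    realistic = [m for m in mols if isinstance(m, Molecule) and m.realistic]

    train_canon = set()
    for s in training_corpus:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            train_canon.add(Chem.MolToSmiles(mol))

    unique_realistic = {m.canonical_smiles: m for m in realistic}
    novel = {c: m for c, m in unique_realistic.items() if c not in train_canon}

    screened = 0
    if novel:
        alert_sets = alert_sets if alert_sets is not None else load_alert_sets()
        screened = sum(
            apply_alert_screen(m, alert_sets).overall_druglike for m in novel.values()
        )

    report = {
        "n_evaluated": n,
        "pct_valid": 100.0 * len(valid) / n,
        "pct_realistic": 100.0 * len(realistic) / n,
        "n_unique_realistic": len(unique_realistic),
        "pct_unique_novel_realistic": 100.0 * len(novel) / n,
        "pct_novel_druglike": (100.0 * screened / len(novel)) if novel else 0.0,
    }
    if training_scores is not None:
        training_scores = np.sort(np.asarray(training_scores, dtype=float))
        new_scores = [v for v in values if v is not None]
        if new_scores:
            mean_score = float(np.mean(new_scores))
            best_score = float(np.max(new_scores))
            ecdf = lambda s: 100.0 * np.searchsorted(  # noqa: E731
                training_scores, s, side="right"
            ) / len(training_scores)
            report["mean_new_score"] = mean_score
            report["best_new_score"] = best_score
            report["mean_score_percentile"] = float(ecdf(mean_score))
            report["best_score_percentile"] = float(ecdf(best_score))
    return report
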