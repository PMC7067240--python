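"""Desk-scale synthetic inputs: a toy SMILES corpus and constrained
Branin-Hoo benchmarks.

The toy corpus is drawn from a small stochastic grammar over C/N/O chains,
single-atom branches and 5-8-membered carbocycles — valid by construction
(and re-checked with RDKit at generation time), with a controlled fraction
of short (< 6 character) strings so the realism predicate has support on
both sides of its cutoff.  The constrained Branin-Hoo problems provide a
ground-truth feasible region and a brute-force grid optimum against which
the full constrained-search stack is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constraint import ConstraintDataset
from .smiles_codec import is_valid


@dataclass
class ToyGrammarSpec:
    """Production settings for the toy SMILES grammar."""

    p_short: float = 0.05  # fraction of deliberately short strings
    p_ring: float = 0.4
    ring_sizes: tuple[int, ...] = (5, 6, 7, 8)
    chain_len: tuple[int, int] = (6, 12)  # heavy atoms in the chain part
    p_branch: float = 0.3
    atoms: tuple[str, ...] = ("C", "C", "C", "N", "O")  # draw weights by repetition
    max_chars: int = 20


_SHORT_STRINGS = ("C", "CC", "CO", "CCO", "CCC", "N", "O", "CN")


def _sample_chain(rng: np.random.Generator, spec: ToyGrammarSpec, n_atoms: int) -> str:
    out = []
    for i in range(n_atoms):
        atom = spec.atoms[rng.integers(len(spec.atoms))]
        out.append(atom)
        # branches only on carbon: keeps every string within valence limits
        if atom == "C" and i < n_atoms - 1 and rng.random() < spec.p_branch:
            out.append(f"({spec.atoms[rng.integers(len(spec.atoms))]})")
    return "".join(out)


def _sample_string(rng: np.random.Generator, spec: ToyGrammarSpec) -> str:
    if rng.random() < spec.p_short:
        return _SHORT_STRINGS[rng.integers(len(_SHORT_STRINGS))]
    parts = []
    if rng.random() < spec.p_ring:
        r = spec.ring_sizes[rng.integers(len(spec.ring_sizes))]
        parts.append("C1" + "C" * (r - 2) + "C1")
    lo, hi = spec.chain_len
    parts.append(_sample_chain(rng, spec, int(rng.integers(lo, hi + 1))))
    s = "".join(parts)
    return s if len(s) <= spec.max_chars else s[: s.rfind(")") + 1] or s[: spec.max_chars]


def toy_smiles_corpus(
    n: int, spec: ToyGrammarSpec | None = None, seed: int = 0
) -> list[str]:
    """Generate ``n`` valid SMILES strings, deterministic under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or ToyGrammarSpec()
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        s = _sample_string(rng, spec)
        if len(s) <= spec.max_chars and is_valid(s):
            out.append(s)
    return out


# --- Branin-Hoo ------------------------------------------------------------

BRANIN_BOUNDS = np.array([[-5.0, 10.0], [0.0, 15.0]])

_A = 1.0
_B = 5.1 / (4.0 * np.pi**2)
_C = 5.0 / np.pi
_R = 6.0
_S = 10.0
_T = 1.0 / (8.0 * np.pi)

#: the three global minimizers of the unconstrained function
BRANIN_MINIMIZERS = np.array(
    [[-np.pi, 12.275], [np.pi, 2.275], [9.42478, 2.475]]
)


def branin_hoo(x1, x2):
    """The standard Branin-Hoo function (three global minima ~= 0.397887)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return (
        _A * (x2 - _B * x1**2 + _C * x1 - _R) ** 2
        + _S * (1.0 - _T) * np.cos(x1)
        + _S
    )


@dataclass
class ToyConstrainedProblem:
    """A 2-d objective, a Boolean feasibility predicate and the brute-force
    constrained optimum on a dense grid."""

    objective: Callable[[np.ndarray], np.ndarray]
    feasible: Callable[[np.ndarray], np.ndarray]
    bounds: np.ndarray
    optimum_value: float
    optimum_location: np.ndarray

    def evaluate(self, z: np.ndarray, seed: int = 0):
        """Maximization-convention evaluator for the BO engine: returns the
        negated objective when feasible, an infeasible outcome otherwise."""
        z = np.asarray(z, dtype=float)
        if bool(self.feasible(z[None, :])[0]):
            return float(-self.objective(z[None, :])[0]), None
        return None, None

    def evaluate_log(self, z: np.ndarray, seed: int = 0):
        """Evaluator on the log scale: score = -log(1 + f(z)).

        The objective spans several orders of magnitude over the domain,
        which makes its fine structure near the optimum invisible to a
        stationary GP after standardization; the monotone log transform
        leaves the constrained minimizer unchanged while letting the
        surrogate resolve the basin.  Invert scores with expm1(-score).
        """
        z = np.asarray(z, dtype=float)
        if bool(self.feasible(z[None, :])[0]):
            return float(-np.log1p(self.objective(z[None, :])[0])), None
        return None, None


def _grid_optimum(objective, feasible, bounds, resolution=2001):
    g1 = np.linspace(bounds[0, 0], bounds[0, 1], resolution)
    g2 = np.linspace(bounds[1, 0], bounds[1, 1], resolution)
    X1, X2 = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([X1.ravel(), X2.ravel()])
    mask = feasible(pts)
    if not mask.any():
        raise ValueError("constraint excludes the entire domain")
    vals = objective(pts[mask])
    k = int(np.argmin(vals))
    return float(vals[k]), pts[mask][k]


def make_constrained_branin(
    constraint: str = "disk",
    params: dict | None = None,
    resolution: int = 2001,
) -> ToyConstrainedProblem:
    """Branin-Hoo with a binding constraint.

    ``disk``: feasible inside a circle (default centered on one minimizer,
    radius 3 — the other two minimizers are excluded).  ``half-plane``:
    feasible where x1 <= params["x1_max"] (default 2.0).
    """
    params = params or {}
    obj = lambda P: branin_hoo(P[:, 0], P[:, 1])  # noqa: E731
    if constraint == "disk":
        center = np.asarray(params.get("center", BRANIN_MINIMIZERS[1]))
        radius = float(params.get("radius", 3.0))
        feas = lambda P: ((P - center) ** 2).sum(axis=1) <= radius**2  # noqa: E731
    elif constraint == "half-plane":
        x1_max = float(params.get("x1_max", 2.0))
        feas = lambda P: P[:, 0] <= x1_max  # noqa: E731
    else:
        raise ValueError(f"unknown constraint {constraint!r}")

    inside = feas(BRANIN_MINIMIZERS)
    if inside.all():
        raise ValueError("constraint must exclude at least one unconstrained minimizer")
    value, loc = _grid_optimum(obj, feas, BRANIN_BOUNDS, resolution)
    return ToyConstrainedProblem(
        objective=obj,
        feasible=feas,
        bounds=BRANIN_BOUNDS.copy(),
        optimum_value=value,
        optimum_location=loc,
    )


def noisy_labeled_problem(
    problem: ToyConstrainedProblem,
    label_noise: float,
    seed: int,
    n: int = 2000,
) -> ConstraintDataset:
    """Uniform points over the problem bounds labelled by the true predicate,
    with labels flipped independently with probability ``label_noise``."""
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    widths = problem.bounds[:, 1] - problem.bounds[:, 0]
    pts = problem.bounds[:, 0] + rng.random((n, 2)) * widths
    labels = problem.feasible(pts).astype(int)
    flips = rng.random(n) < label_noise
    labels[flips] = 1 - labels[flips]
    return ConstraintDataset(
        points=pts, labels=labels, provenance=["uniform-latent-sample"] * n
    )
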