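"""Constrained Bayesian optimization in the VAE latent space.

The engine minimizes the negated, standardized objective f(z) subject to the
probabilistic constraint Pr(C(z)) >= 1 − delta.  Acquisition is expected
improvement with constraints, EIC(z) = Pr(C(z)) · EI(z) (independent-product
form), where the incumbent eta is the minimum of the GP posterior mean over
the constraint-feasible surrogate training inputs.  When no training input is
feasible the engine ignores the objective and maximizes Pr(C(z)) alone until
the feasible region is located.  Batches are proposed with Kriging-Believer:
each selected point's outcome is hallucinated as the GP posterior mean and
the GP is conditioned on it before the next point is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .constraint import ConstraintModel
from .gp import GPConfig, SurrogateGP, fit_surrogate
from .smiles_codec import Molecule
from .vae import LatentPoint, VAEModel


class BOError(RuntimeError):
    def __init__(self, message: str, partial_batch: list | None = None):
        super().__init__(message)
        self.partial_batch = partial_batch or []


# --- acquisition functions -------------------------------------------------


def expected_improvement(gp: SurrogateGP, z: np.ndarray, eta: float) -> float:
    """Closed-form EI toward the minimum: E[max(0, eta − f(z))]."""
    return float(_ei_vec(gp, np.atleast_2d(z), eta)[0])


def _ei_vec(gp: SurrogateGP, Z: np.ndarray, eta: float) -> np.ndarray:
    mu, sigma = gp.posterior(Z)
    out = np.maximum(eta - mu, 0.0)
    pos = sigma > 0
    u = (eta - mu[pos]) / sigma[pos]
    out[pos] = (eta - mu[pos]) * norm.cdf(u) + sigma[pos] * norm.pdf(u)
    return np.maximum(out, 0.0)


@dataclass
class AcquisitionState:
    """Incumbent and mode; feasibility-only iff no feasible point is known."""

    incumbent: float | None
    delta: float

    @property
    def mode(self) -> str:
        return "EIC" if self.incumbent is not None else "feasibility-only"


def eic(
    gp: SurrogateGP, cm: ConstraintModel, z: np.ndarray, state: AcquisitionState
) -> float:
    """EIC(z) = Pr(C(z)) × EI(z); requires an incumbent."""
    if state.incumbent is None:
        raise BOError(
            "EIC undefined without an incumbent; use feasibility_acquisition"
        )
    return float(_eic_vec(gp, cm, np.atleast_2d(z), state.incumbent)[0])


def _eic_vec(gp, cm, Z, eta):
    return cm.predict_probability(Z) * _ei_vec(gp, Z, eta)


def feasibility_acquisition(cm: ConstraintModel, z: np.ndarray) -> float:
    """Pr(C(z)) — the objective-blind acquisition used before any feasible
    point is known."""
    return float(cm.predict_probability(np.atleast_2d(z))[0])


def select_incumbent(
    gp: SurrogateGP, cm: ConstraintModel, delta: float, candidates: np.ndarray
) -> float | None:
    """Minimum posterior mean over candidates with Pr(C) >= 1 − delta, or
    ``None`` when no candidate is feasible."""
    candidates = np.atleast_2d(candidates)
    if len(candidates) == 0:
        raise BOError("candidate set for incumbent selection is empty")
    feasible = cm.predict_probability(candidates) >= 1.0 - delta
    if not feasible.any():
        return None
    mu, _ = gp.posterior(candidates[feasible])
    return float(mu.min())


# --- batch proposal --------------------------------------------------------


@dataclass
class BOConfig:
    """Engine settings.

    The full-scale pipeline runs 20 iterations of batches of 50; desk-scale
    runs shrink both.  ``n_candidates`` uniform points pre-screen the
    acquisition surface each step and the best ``n_polish`` are refined with
    L-BFGS-B.
    """

    n_iterations: int = 20
    batch_size: int = 50
    bounds: np.ndarray | None = None  # (d, 2)
    delta: float | None = None  # default: the constraint model's delta
    n_candidates: int = 256
    n_polish: int = 3
    n_initial: int = 20
    gp: GPConfig = field(default_factory=GPConfig)


def _maximize_acquisition(
    acq_vec: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int,
    n_polish: int,
    anchors: np.ndarray | None = None,
) -> np.ndarray:
    d = bounds.shape[0]
    widths = bounds[:, 1] - bounds[:, 0]
    cand = bounds[:, 0] + rng.random((n_candidates, d)) * widths
    if anchors is not None and len(anchors):
        # anchor points (e.g. the incumbent basin) plus local jitter join the
        # pool so the polish stage can exploit as well as explore
        jitter = anchors[None, :, :] + rng.normal(
            scale=0.02 * widths, size=(3, len(anchors), d)
        )
        extra = np.vstack([anchors, jitter.reshape(-1, d)])
        cand = np.vstack([cand, np.clip(extra, bounds[:, 0], bounds[:, 1])])
    vals = acq_vec(cand)
    order = np.argsort(vals)[::-1]
    best_x, best_v = cand[order[0]], vals[order[0]]
    for i in order[:n_polish]:
        res = minimize(
            lambda x: -float(acq_vec(x[None, :])[0]),
            cand[i],
            method="L-BFGS-B",
            bounds=list(map(tuple, bounds)),
            options={"maxiter": 50},
        )
        if np.isfinite(res.fun) and -res.fun > best_v:
            best_x, best_v = res.x, -res.fun
    return np.asarray(best_x, dtype=float)


def propose_batch_kriging_believer(
    gp: SurrogateGP,
    cm: ConstraintModel,
    state: AcquisitionState,
    batch_size: int,
    bounds: np.ndarray,
    seed: int,
    n_candidates: int = 256,
    n_polish: int = 3,
) -> list[np.ndarray]:
    """Sequentially select ``batch_size`` distinct points, hallucinating each
    selected point's outcome as the GP posterior mean before the next pick.

    Coincident picks (possible in feasibility-only mode, where hallucination
    does not change the acquisition) are displaced by a small seeded Gaussian
    jitter — the documented tie-break.
    """
    if batch_size < 1:
        raise BOError("batch_size must be >= 1")
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(seed)
    widths = bounds[:, 1] - bounds[:, 0]
    batch: list[np.ndarray] = []
    gp_h = gp
    if state.mode == "EIC" and getattr(gp, "X", None) is not None and len(gp.X):
        anchors = gp.X[np.argsort(np.asarray(gp.y))[:3]]  # best observed inputs
    else:
        anchors = None
    for _ in range(batch_size):
        if state.mode == "EIC":
            g = gp_h
            acq = lambda Z: _eic_vec(g, cm, Z, state.incumbent)  # noqa: E731
        else:
            acq = lambda Z: cm.predict_probability(Z)  # noqa: E731
        try:
            x = _maximize_acquisition(
                acq, bounds, rng, n_candidates, n_polish, anchors
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            raise BOError(
                f"acquisition maximization failed at batch position {len(batch)}: {exc}",
                partial_batch=batch,
            ) from exc
        if batch and min(np.linalg.norm(x - b) for b in batch) < 1e-9:
            x = np.clip(
                x + rng.normal(scale=1e-3 * widths), bounds[:, 0], bounds[:, 1]
            )
        batch.append(x)
        gp_h = gp_h.condition(x, gp_h.posterior_mean(x))
    return batch


# --- run loop --------------------------------------------------------------


@dataclass
class IterationRecord:
    batch: np.ndarray  # (batch_size, d)
    molecules: list  # Molecule or None per point (generic runs: metadata)
    values: list  # raw objective value or None (infeasible) per point
    constraint_probs: np.ndarray
    eta: float | None
    mode: str


@dataclass
class BOHistory:
    """Per-iteration record of a constrained BO run."""

    iterations: list[IterationRecord] = field(default_factory=list)
    incumbent_trace: list[float] = field(default_factory=list)  # internal scale
    best_feasible_trace: list[float] = field(default_factory=list)  # raw scale
    y_mean: float = 0.0
    y_std: float = 1.0

    @property
    def n_evaluated(self) -> int:
        return sum(len(it.batch) for it in self.iterations)

    def best_feasible(self) -> float | None:
        vals = [v for it in self.iterations for v in it.values if v is not None]
        return max(vals) if vals else None

    def all_molecules(self) -> list[Molecule]:
        return [
            m
            for it in self.iterations
            for m in it.molecules
            if isinstance(m, Molecule)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, it in enumerate(self.iterations):
            for j in range(len(it.batch)):
                mol = it.molecules[j]
                rows.append(
                    {
                        "iteration": i,
                        "smiles": mol.smiles if isinstance(mol, Molecule) else None,
                        "valid": mol.valid if isinstance(mol, Molecule) else None,
                        "realistic": mol.realistic
                        if isinstance(mol, Molecule)
                        else None,
                        "value": it.values[j],
                        "constraint_prob": float(it.constraint_probs[j]),
                        "mode": it.mode,
                    }
                )
        return pd.DataFrame(rows)


def run_bo_generic(
    evaluate: Callable[[np.ndarray, int], tuple[float | None, object]],
    cm: ConstraintModel,
    config: BOConfig,
    seed: int,
    X0: np.ndarray,
    y0: np.ndarray,
) -> BOHistory:
    """Constrained BO over an arbitrary evaluator.

    ``evaluate(z, seed)`` returns ``(raw_value_or_None, metadata)``; raw
    values are "larger is better" and are negated/standardized internally.
    ``X0, y0`` form the initial design (raw scale, all feasible).
    """
    if config.bounds is None:
        raise BOError("config.bounds must be set")
    bounds = np.asarray(config.bounds, dtype=float)
    delta = config.delta if config.delta is not None else cm.delta
    rng = np.random.default_rng(seed)

    y_mean = float(np.mean(y0))
    y_std = float(np.std(y0)) or 1.0
    to_internal = lambda v: -(v - y_mean) / y_std  # noqa: E731

    X = np.atleast_2d(np.asarray(X0, dtype=float)).copy()
    y = np.array([to_internal(v) for v in y0], dtype=float)
    history = BOHistory(y_mean=y_mean, y_std=y_std)
    best_internal = np.inf
    best_raw = -np.inf

    for it in range(config.n_iterations):
        gp = fit_surrogate(X, y, config.gp, seed=int(rng.integers(2**31 - 1)))
        eta = select_incumbent(gp, cm, delta, X)
        if eta is None and len(X):
            # every surrogate input is a successfully evaluated (feasible)
            # point, so the feasible region is located even when none of them
            # clears the probabilistic threshold; fall back to the minimum
            # posterior mean over the observed feasible points rather than
            # abandoning the objective
            eta = float(gp.posterior(X)[0].min())
        state = AcquisitionState(incumbent=eta, delta=delta)
        batch = propose_batch_kriging_believer(
            gp,
            cm,
            state,
            config.batch_size,
            bounds,
            seed=int(rng.integers(2**31 - 1)),
            n_candidates=config.n_candidates,
            n_polish=config.n_polish,
        )
        values, metas = [], []
        for x in batch:
            v, meta = evaluate(x, int(rng.integers(2**31 - 1)))
            values.append(v)
            metas.append(meta)
            if v is not None:
                X = np.vstack([X, x])
                y = np.append(y, to_internal(v))
                best_internal = min(best_internal, to_internal(v))
                best_raw = max(best_raw, v)
        probs = cm.predict_probability(np.stack(batch))
        history.iterations.append(
            IterationRecord(
                batch=np.stack(batch),
                molecules=metas,
                values=values,
                constraint_probs=probs,
                eta=eta,
                mode=state.mode,
            )
        )
        history.incumbent_trace.append(best_internal)
        history.best_feasible_trace.append(best_raw)
    return history


def run_bo(
    objective,
    model: VAEModel,
    cm: ConstraintModel,
    config: BOConfig,
    seed: int,
    corpus: list[str] | None = None,
    initial_design: tuple[np.ndarray, np.ndarray] | None = None,
) -> BOHistory:
    """Constrained BO over molecules decoded from the VAE latent space.

    The initial design is either supplied directly as ``(X0, y0)`` (raw
    scores) or built from the encodings of a seeded random subset of
    ``corpus`` of size ``config.n_initial``, scored through the decoder.
    """
    from .objectives import evaluate_latent

    if model.latent_dim != cm.latent_dim:
        raise BOError(
            f"latent dimension mismatch: VAE d={model.latent_dim}, "
            f"constraint d={cm.latent_dim}"
        )
    if initial_design is None:
        if corpus is None:
            raise BOError("provide either corpus or initial_design")
        initial_design = initial_design_from_corpus(
            objective, model, corpus, config.n_initial, seed
        )
    X0, y0 = initial_design

    if config.bounds is None:
        from .constraint import latent_bounding_box

        config.bounds = latent_bounding_box(np.atleast_2d(X0))

    def evaluate(zvec: np.ndarray, pt_seed: int):
        ev = evaluate_latent(
            objective, model, LatentPoint(zvec, provenance="BO-proposed"), pt_seed
        )
        return ev.value, ev.molecule

    return run_bo_generic(evaluate, cm, config, seed, X0, y0)


def initial_design_from_corpus(
    objective, model: VAEModel, corpus: list[str], n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a seeded random corpus subset and score the molecules directly."""
    from .objectives import score

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(corpus), size=min(n, len(corpus)), replace=False)
    X, y = [], []
    for i in idx:
        mol = Molecule.from_smiles(corpus[i])
        if not mol.valid:
            continue
        X.append(model.encode(corpus[i]).z)
        y.append(score(objective, mol))
    if len(X) < 2:
        raise BOError("initial design needs at least 2 scoreable molecules")
    return np.stack(X), np.array(y)
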