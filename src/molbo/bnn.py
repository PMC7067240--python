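"""Mean-field variational Bayesian MLP classifier.

The feasibility constraint needs a classifier whose confidence *decays* away
from its training data: a point-estimate network extrapolates its decision
boundary confidently into regions it has never seen, which would let the
acquisition function wander into latent dead zones.  Here every weight
carries a diagonal-Gaussian posterior q(w) = N(mu, sigma^2) trained by
stochastic variational inference (the local reparameterization trick for
low-variance gradients), and the predictive probability is the average of
the logistic output over posterior weight samples.  Far from the data the
pre-activation variance h^2 sigma^2 grows with ||h||, the sampled logits
disagree, and the averaged probability falls toward 0.5 — the behaviour the
constrained search relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class BayesianMLPClassifier:
    """Two-hidden-layer ReLU network with a logistic output and a mean-field
    Gaussian posterior over all weights."""

    hidden_layers: tuple[int, int] = (100, 100)
    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 1e-3
    prior_sigma: float = 1.0
    kl_weight: float = 1.0  # <1 tempers the posterior (counters VI underconfidence)
    n_posterior_samples: int = 50
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)
    _weight_samples: list = field(default_factory=list, repr=False)
    n_features_: int | None = None

    # --- initialization ----------------------------------------------------

    def _layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.n_features_, *self.hidden_layers, 1]
        return list(zip(dims[:-1], dims[1:]))

    def _init_params(self, rng: np.random.Generator) -> None:
        self.params = {}
        for i, (fan_in, fan_out) in enumerate(self._layer_dims()):
            s = np.sqrt(2.0 / fan_in)
            self.params[f"muW{i}"] = rng.normal(0, s, (fan_in, fan_out))
            self.params[f"rhoW{i}"] = np.full((fan_in, fan_out), -5.0)
            self.params[f"mub{i}"] = np.zeros(fan_out)
            self.params[f"rhob{i}"] = np.full(fan_out, -5.0)

    # --- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BayesianMLPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, self.n_features_ = X.shape
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)
        opt = _Adam(self.params, self.learning_rate)
        n_layers = len(self._layer_dims())

        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                grads = self._step_grads(X[idx], y[idx], n, rng, n_layers)
                opt.step(self.params, grads)

        # freeze posterior weight samples: predictions become deterministic
        sample_rng = np.random.default_rng(self.seed + 1)
        self._weight_samples = [
            self._draw_weights(sample_rng) for _ in range(self.n_posterior_samples)
        ]
        return self

    def _step_grads(self, Xb, yb, n_total, rng, n_layers):
        p = self.params
        B = len(yb)
        # forward with local reparameterization
        h = Xb
        cache = []
        for i in range(n_layers):
            sW = _softplus(p[f"rhoW{i}"])
            sb = _softplus(p[f"rhob{i}"])
            m = h @ p[f"muW{i}"] + p[f"mub{i}"]
            v = (h**2) @ sW**2 + sb**2
            eps = rng.standard_normal(m.shape)
            a = m + np.sqrt(v) * eps
            out = a if i == n_layers - 1 else np.maximum(a, 0.0)
            cache.append((h, sW, sb, v, eps, a))
            h = out
        logit = h[:, 0]
        prob = _sigmoid(logit)

        grads = {}
        delta = ((prob - yb) / B)[:, None]  # d mean-BCE / d logit
        for i in reversed(range(n_layers)):
            hin, sW, sb, v, eps, a = cache[i]
            if i != n_layers - 1:
                delta = delta * (a > 0)
            dv = delta * eps * 0.5 / np.sqrt(v)
            grads[f"muW{i}"] = hin.T @ delta
            grads[f"mub{i}"] = delta.sum(axis=0)
            dsW2 = (hin**2).T @ dv
            dsb2 = dv.sum(axis=0)
            grads[f"rhoW{i}"] = dsW2 * 2.0 * sW * _sigmoid(p[f"rhoW{i}"])
            grads[f"rhob{i}"] = dsb2 * 2.0 * sb * _sigmoid(p[f"rhob{i}"])
            if i > 0:
                delta = delta @ p[f"muW{i}"].T + 2.0 * hin * (dv @ (sW**2).T)

        # KL(q || N(0, prior_sigma^2)) gradients, scaled by kl_weight/N
        sp2 = self.prior_sigma**2
        n_total = n_total / self.kl_weight
        for i in range(n_layers):
            for kind in ("W", "b"):
                mu = self.params[f"mu{kind}{i}"]
                rho = self.params[f"rho{kind}{i}"]
                s = _softplus(rho)
                grads[f"mu{kind}{i}"] += mu / sp2 / n_total
                ds = (s / sp2 - 1.0 / s) / n_total
                grads[f"rho{kind}{i}"] += ds * _sigmoid(rho)
        return grads

    # --- prediction --------------------------------------------------------

    def _draw_weights(self, rng: np.random.Generator) -> dict:
        draw = {}
        for i in range(len(self._layer_dims())):
            for kind in ("W", "b"):
                mu = self.params[f"mu{kind}{i}"]
                s = _softplus(self.params[f"rho{kind}{i}"])
                draw[f"{kind}{i}"] = mu + s * rng.standard_normal(mu.shape)
        return draw

    def _forward(self, X: np.ndarray, weights: dict) -> np.ndarray:
        h = X
        n_layers = len(self._layer_dims())
        for i in range(n_layers):
            a = h @ weights[f"W{i}"] + weights[f"b{i}"]
            h = a if i == n_layers - 1 else np.maximum(a, 0.0)
        return h[:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of the logistic output over the frozen posterior samples;
        returns an (n, 2) array in scikit-learn convention."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        probs = np.mean(
            [_sigmoid(self._forward(X, w)) for w in self._weight_samples], axis=0
        )
        return np.column_stack([1.0 - probs, probs])
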