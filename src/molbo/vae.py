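"""A character-level SMILES variational autoencoder.

The model maps a fixed-length one-hot SMILES matrix through an MLP encoder to
the mean and diagonal variance of a Gaussian approximate posterior q(z|m),
and maps a latent point z through an MLP decoder to an independent categorical
distribution over the alphabet at every sequence position.  Training maximizes
the evidence lower bound (per-position cross-entropy reconstruction term plus
the analytic KL divergence to a standard-normal prior, KL weight 1) with Adam.

Decoding is stochastic: each attempt samples every position from its
categorical at temperature 1 and truncates at the first pad/stop token.  A
single latent point therefore decodes to a *distribution* over strings — the
property the constrained-search layer exploits and diagnoses.

The implementation is a compact feed-forward network sized for desk-scale
corpora; the surrounding pipeline depends only on the encode / decode-attempts
contract, not on the architecture.
"""

from __future__ import annotations

import io
import json
import zipfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .smiles_codec import (
    Alphabet,
    CodecError,
    Molecule,
    encode_onehot,
    indices_to_string,
    tokenize,
)


@dataclass
class VAEConfig:
    """Architecture and training settings.

    latent_dim
        Dimension d of the latent space.  The full-scale pipeline this
        package models uses d = 56; desk-scale defaults are smaller.
    hidden_dim
        Width of the single hidden layer in encoder and decoder.
    max_len
        Fixed sequence length L; strings are padded to it.
    epochs, batch_size, learning_rate
        Adam training schedule.
    holdout_fraction
        Fraction of the corpus held out for the ELBO progress check.
    """

    latent_dim: int = 8
    hidden_dim: int = 192
    max_len: int = 24
    epochs: int = 30
    batch_size: int = 100
    learning_rate: float = 5e-3
    holdout_fraction: float = 0.1


@dataclass(frozen=True)
class LatentPoint:
    """A d-dimensional latent vector with an optional provenance tag."""

    z: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or not np.isfinite(z).all():
            raise ValueError("latent point must be a finite 1-d vector")
        object.__setattr__(self, "z", z)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
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
class VAEModel:
    """Trained SMILES VAE: parameters, alphabet, config and ELBO trace."""

    alphabet: Alphabet
    config: VAEConfig
    params: dict[str, np.ndarray]
    training_log: dict[str, list[float]] = field(default_factory=dict)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    # --- encoder -----------------------------------------------------------

    def encoder_moments(self, x_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and log-variance of q(z|m) for a batch of flattened one-hots."""
        p = self.params
        h = _relu(x_flat @ p["W1"] + p["b1"])
        mu = h @ p["Wm"] + p["bm"]
        logvar = np.clip(h @ p["Wv"] + p["bv"], -10.0, 10.0)
        return mu, logvar

    def encode(self, smiles: str) -> LatentPoint:
        """Deterministic embedding: the mean of q(z|m)."""
        x = self._flatten(smiles)
        mu, _ = self.encoder_moments(x[None, :])
        return LatentPoint(z=mu[0], provenance="encoded-from-data")

    def encode_sample(self, smiles: str, seed: int) -> LatentPoint:
        """Stochastic embedding: mean + diagonal-Gaussian noise, seeded."""
        x = self._flatten(smiles)
        mu, logvar = self.encoder_moments(x[None, :])
        rng = np.random.default_rng(seed)
        z = mu[0] + np.exp(0.5 * logvar[0]) * rng.standard_normal(self.latent_dim)
        return LatentPoint(z=z, provenance="encoded-from-data")

    def _flatten(self, smiles: str) -> np.ndarray:
        seq = encode_onehot(smiles, self.alphabet, self.config.max_len)
        return seq.matrix.astype(float).ravel()

    # --- decoder -----------------------------------------------------------

    def decoder_probs(self, z: np.ndarray) -> np.ndarray:
        """Per-position categorical probabilities, shape (B, L, A)."""
        p = self.params
        z = np.atleast_2d(z)
        h = _relu(z @ p["W2"] + p["b2"])
        logits = (h @ p["W3"] + p["b3"]).reshape(
            z.shape[0], self.config.max_len, self.alphabet.size
        )
        return _softmax(logits)

    def decode_attempts(self, z: LatentPoint, n_attempts: int, seed: int) -> list[str]:
        """Sample ``n_attempts`` strings from the decoder distribution at z,
        temperature 1, truncating each at the first pad token."""
        if n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")
        probs = self.decoder_probs(z.z)[0]  # (L, A)
        rng = np.random.default_rng(seed)
        L, A = probs.shape
        # inverse-CDF sampling, vectorized over attempts and positions
        cdf = np.cumsum(probs, axis=1)
        u = rng.random((n_attempts, L, 1))
        idx = (u > cdf[None, :, :]).sum(axis=2)
        return [indices_to_string(row, self.alphabet) for row in idx]

    def most_probable_decoding(
        self, z: LatentPoint, n_attempts: int, seed: int
    ) -> Molecule:
        """Modal string among ``n_attempts`` samples (ties broken
        lexicographically), wrapped with validity / realism flags."""
        attempts = self.decode_attempts(z, n_attempts, seed)
        counts = Counter(attempts)
        best, _ = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return Molecule.from_smiles(best)

    # --- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + alphabet JSON + config."""
        path = Path(path)
        buf = io.BytesIO()
        np.savez(buf, **self.params)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("alphabet.json", self.alphabet.to_json())
            zf.writestr("config.json", json.dumps(self.config.__dict__))
            zf.writestr("training_log.json", json.dumps(self.training_log))

    @classmethod
    def load(cls, path: str | Path) -> "VAEModel":
        with zipfile.ZipFile(Path(path)) as zf:
            weights = np.load(io.BytesIO(zf.read("weights.npz")))
            params = {k: weights[k] for k in weights.files}
            alphabet = Alphabet.from_json(zf.read("alphabet.json").decode())
            config = VAEConfig(**json.loads(zf.read("config.json")))
            log = json.loads(zf.read("training_log.json"))
        return cls(alphabet=alphabet, config=config, params=params, training_log=log)


def _init_params(cfg: VAEConfig, alphabet_size: int, rng: np.random.Generator):
    n_in = cfg.max_len * alphabet_size
    H, d = cfg.hidden_dim, cfg.latent_dim

    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    return {
        "W1": glorot(n_in, H), "b1": np.zeros(H),
        "Wm": glorot(H, d), "bm": np.zeros(d),
        "Wv": glorot(H, d), "bv": np.zeros(d),
        "W2": glorot(d, H), "b2": np.zeros(H),
        "W3": glorot(H, n_in), "b3": np.zeros(n_in),
    }


def _elbo_and_grads(params, x, cfg: VAEConfig, A: int, rng: np.random.Generator):
    """Minibatch negative-ELBO and parameter gradients (manual backprop)."""
    B = x.shape[0]
    h1_pre = x @ params["W1"] + params["b1"]
    h1 = _relu(h1_pre)
    mu = h1 @ params["Wm"] + params["bm"]
    logvar = np.clip(h1 @ params["Wv"] + params["bv"], -10.0, 10.0)
    eps = rng.standard_normal(mu.shape)
    std = np.exp(0.5 * logvar)
    z = mu + std * eps

    h2_pre = z @ params["W2"] + params["b2"]
    h2 = _relu(h2_pre)
    logits = h2 @ params["W3"] + params["b3"]
    probs = _softmax(logits.reshape(B, cfg.max_len, A)).reshape(B, -1)

    ce = -np.sum(x * np.log(probs + 1e-12)) / B
    kl = 0.5 * np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar) / B
    loss = ce + kl  # negative ELBO per example

    dlogits = (probs - x) / B
    g = {}
    g["W3"] = h2.T @ dlogits
    g["b3"] = dlogits.sum(axis=0)
    dh2 = (dlogits @ params["W3"].T) * (h2_pre > 0)
    g["W2"] = z.T @ dh2
    g["b2"] = dh2.sum(axis=0)
    dz = dh2 @ params["W2"].T

    dmu = dz + mu / B
    dlogvar = dz * eps * std * 0.5 + 0.5 * (np.exp(logvar) - 1.0) / B
    g["Wm"] = h1.T @ dmu
    g["bm"] = dmu.sum(axis=0)
    g["Wv"] = h1.T @ dlogvar
    g["bv"] = dlogvar.sum(axis=0)
    dh1 = (dmu @ params["Wm"].T + dlogvar @ params["Wv"].T) * (h1_pre > 0)
    g["W1"] = x.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return loss, g


def _holdout_neg_elbo(model: VAEModel, x: np.ndarray, seed: int) -> float:
    rng = np.random.default_rng(seed)
    loss, _ = _elbo_and_grads(
        model.params, x, model.config, model.alphabet.size, rng
    )
    return float(loss)


def train_vae(
    corpus: list[str],
    config: VAEConfig,
    seed: int,
    alphabet: Alphabet | None = None,
) -> VAEModel:
    """Train the VAE on a SMILES corpus; deterministic under ``seed``.

    Raises with the offending strings listed when any corpus entry cannot be
    encoded (unknown token or over-length).
    """
    from .smiles_codec import build_alphabet

    if not corpus:
        raise CodecError("empty corpus")
    if alphabet is None:
        alphabet = build_alphabet(corpus)

    offenders = []
    for s in corpus:
        toks = tokenize(s, alphabet.merge_tokens)
        if len(toks) > config.max_len or any(
            t not in alphabet.characters for t in toks
        ):
            offenders.append(s)
    if offenders:
        raise CodecError(f"non-encodable corpus entries: {offenders[:10]}")

    rng = np.random.default_rng(seed)
    params = _init_params(config, alphabet.size, rng)
    model = VAEModel(alphabet=alphabet, config=config, params=params)

    X = np.stack([model._flatten(s) for s in corpus])
    n = X.shape[0]
    n_hold = max(1, int(round(config.holdout_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    hold, train = X[perm[:n_hold]], X[perm[n_hold:]]
    if train.shape[0] == 0:
        train, hold = X, X

    opt = _Adam(params, config.learning_rate)
    train_trace, hold_trace = [], []
    for epoch in range(config.epochs):
        order = rng.permutation(train.shape[0])
        losses = []
        for start in range(0, train.shape[0], config.batch_size):
            batch = train[order[start : start + config.batch_size]]
            loss, grads = _elbo_and_grads(params, batch, config, alphabet.size, rng)
            opt.step(params, grads)
            losses.append(loss)
        train_trace.append(float(np.mean(losses)))
        if hold.shape[0]:
            hold_trace.append(_holdout_neg_elbo(model, hold, seed + 7919 + epoch))
    model.training_log = {"train_neg_elbo": train_trace, "holdout_neg_elbo": hold_trace}
    return model


# module-level conveniences mirroring the pipeline vocabulary ---------------

def encode(model: VAEModel, smiles: str) -> LatentPoint:
    return model.encode(smiles)


def decode_attempts(
    model: VAEModel, z: LatentPoint, n_attempts: int, seed: int
) -> list[str]:
    return model.decode_attempts(z, n_attempts, seed)


def most_probable_decoding(
    model: VAEModel, z: LatentPoint, n_attempts: int, seed: int
) -> Molecule:
    return model.most_probable_decoding(z, n_attempts, seed)
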