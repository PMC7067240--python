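import numpy as np
import pytest

import molbo
from molbo.constraint import desk_scale_config, train_constraint_classifier


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return molbo.toy_smiles_corpus(1000, seed=1)


@pytest.fixture(scope="session")
def toy_vae(toy_corpus):
    return molbo.train_vae(toy_corpus, molbo.VAEConfig(), seed=0)


@pytest.fixture(scope="session")
def branin_problem():
    return molbo.make_constrained_branin("disk")


@pytest.fixture(scope="session")
def branin_constraint(branin_problem):
    data = molbo.noisy_labeled_problem(branin_problem, label_noise=0.1, seed=11, n=2000)
    return train_constraint_classifier(data, desk_scale_config(), seed=11)


class StubDecoder:
    """Minimal VAE stand-in whose decode attempts are scripted."""

    def __init__(self, attempts: list[str], latent_dim: int = 4):
        self.attempts = attempts
        self.latent_dim = latent_dim

    def decode_attempts(self, z, n_attempts, seed):
        reps = -(-n_attempts // len(self.attempts))
        return (self.attempts * reps)[:n_attempts]

    def most_probable_decoding(self, z, n_attempts, seed):
        from collections import Counter

        counts = Counter(self.decode_attempts(z, n_attempts, seed))
        best, _ = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return molbo.Molecule.from_smiles(best)


@pytest.fixture
def stub_decoder_factory():
    return StubDecoder


class ConstantConstraint:
    """Constraint stand-in returning a fixed probability everywhere."""

    def __init__(self, p: float, latent_dim: int = 2, delta: float = 0.05):
        self.p = p
        self.latent_dim = latent_dim
        self.delta = delta

    def predict_probability(self, Z):
        return np.full(len(np.atleast_2d(Z)), self.p)


@pytest.fixture
def constant_constraint_factory():
    return ConstantConstraint
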