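import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrmediate import HarmonizedPair, TruthParams, simulate_triplet_gwas

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_pair(gamma, sigma_x, Gamma, sigma_y, exposure="exp", outcome="out"):
    gamma = np.asarray(gamma, float)
    # a zero exposure SE means "treat gamma_hat as exact"; the container
    # requires strictly positive SEs, so clip to a negligible value
    sigma_x = np.maximum(np.asarray(sigma_x, float), 1e-12)
    return HarmonizedPair(
        exposure_id=exposure, outcome_id=outcome,
        rsids=np.array([f"rs{i}" for i in range(len(gamma))], dtype=object),
        gamma_hat=gamma, sigma_x=sigma_x,
        Gamma_hat=np.asarray(Gamma, float), sigma_y=np.asarray(sigma_y, float),
    )


def random_pair(rng, J=30, beta=0.3, sx=0.02, sy=0.05):
    """A clean simulated pair with known causal slope."""
    gamma = rng.normal(0.15, 0.05, J)
    gamma_hat = gamma + rng.normal(0, sx, J)
    Gamma_hat = beta * gamma + rng.normal(0, sy, J)
    return make_pair(gamma_hat, np.full(J, sx), Gamma_hat, np.full(J, sy))


def sim_pair_from_truth(truth: TruthParams, leg: str = "exposure->outcome"):
    """Harmonized pair over the relevant designed instrument set."""
    from mrmediate.simulate import designed_instrument_pair

    return designed_instrument_pair(truth, leg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def triplet_default():
    return simulate_triplet_gwas(TruthParams(seed=7))
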