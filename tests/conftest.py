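import numpy as np
import pytest

from resgc import ModelParams, SimConfig, simulate_sde


@pytest.fixture(scope="session")
def base_params():
    """Default study conditions: eps = 0.01 (every leader has a hundred
    followers), unit flip rate."""
    return ModelParams(p=1.0, n1=100, n2=10_000, mu=0.0)


def with_mu(params: ModelParams, mu: float) -> ModelParams:
    return ModelParams(p=params.p, n1=params.n1, n2=params.n2, mu=mu)


@pytest.fixture(scope="session")
def delta_t():
    """Observation interval giving h = p*delta_t = 0.145 (package default)."""
    return 0.145


@pytest.fixture(scope="session")
def traj_mu3(base_params, delta_t):
    """One shared seeded trajectory at mu = 3 for simulation-backed tests."""
    params = with_mu(base_params, 3.0)
    cfg = SimConfig(delta_t=delta_t, n_obs=50_000, seed=1234)
    return simulate_sde(params, cfg)


def random_triangular_model(rng, h=0.145):
    """Random stable triangular VAR(1) with a random SPD residual covariance.

    Resamples until the effective coefficient b' = b - (Sigma12/Sigma22) c
    also satisfies |b'| < 1, the domain on which the closed-form and
    spectral GC routes are defined.
    """
    from resgc import VAR1Model

    while True:
        b = rng.uniform(-0.95, 0.95)
        a = rng.uniform(-0.95, 0.95)
        c = rng.uniform(-1.0, 1.0)
        L = rng.normal(size=(2, 2))
        Sigma = L @ L.T + 0.05 * np.eye(2)
        if abs(b - Sigma[0, 1] / Sigma[1, 1] * c) < 0.999:
            return VAR1Model(b=b, c=c, a=a, Sigma=Sigma, h=h)
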