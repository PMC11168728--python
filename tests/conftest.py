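import numpy as np
import pytest

from mesoflow.config import EmbeddingCandidates, KernelConfig, RunConfig
from mesoflow.synthetic import hub_network, simulate_coupled_network


@pytest.fixture(scope="session")
def recovery_config() -> RunConfig:
    """Estimator settings for the synthetic structure-recovery regime:
    radius 0.5 x SD (adequate neighbour counts at 400 samples), 100
    time-shift surrogates, candidate lags up to 20 ms (the generators couple
    at lags <= 5 ms)."""
    return RunConfig(
        kernel=KernelConfig(r_fraction=0.5, surrogates=100),
        embedding=EmbeddingCandidates(max_lag=20),
    )


@pytest.fixture(scope="session")
def go_epoch_tensor() -> np.ndarray:
    """One 10-node hub-network session, go condition (channels x 400 x 20)."""
    truth = hub_network(n_nodes=10)
    return simulate_coupled_network(truth, 400, 20, 1.0, seed=101,
                                    conditions=("go",))["go"]


def ar_coupled_pair(seed: int, n: int, a: float = 0.5, b: float = 0.5,
                    c: float = 0.5, burn: int = 200) -> np.ndarray:
    """Linear-Gaussian VAR(1): X AR(b) driving Y (AR a, coupling c, lag 1)."""
    rng = np.random.default_rng(seed)
    z = np.zeros((2, n + burn))
    e = rng.standard_normal((2, n + burn))
    for t in range(1, n + burn):
        z[0, t] = b * z[0, t - 1] + e[0, t]
        z[1, t] = a * z[1, t - 1] + c * z[0, t - 1] + e[1, t]
    return z[:, burn:]
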