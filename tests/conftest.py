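import numpy as np
import pytest

from phispike import (
    BinnedMatrix,
    GaussianModel,
    GeneratorSpec,
    SessionData,
    SpikeTrain,
    binarize,
    gen_coupled,
    gen_independent,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_session():
    """Three neurons, 1 s, a handful of spikes."""
    return SessionData(
        trains=(
            SpikeTrain("n0", np.array([0.01, 0.05, 0.40])),
            SpikeTrain("n1", np.array([0.11, 0.12, 0.70])),
            SpikeTrain("n2", np.array([0.25])),
        ),
        events=((0.3, "reward"), (0.8, "reward")),
        t_start=0.0,
        t_end=1.0,
    )


@pytest.fixture
def coin_matrix(rng):
    """15 independent fair-coin neurons, 5000 bins."""
    states = (rng.random((15, 5000)) < 0.5).astype(np.int8)
    return BinnedMatrix(states=states, bin_size=0.03,
                        neuron_ids=tuple(f"n{i}" for i in range(15)))


@pytest.fixture
def coupled_binned():
    """Well-conditioned 6-neuron coupled matrix for Phi pipelines."""
    spec = GeneratorSpec(n_neurons=6, duration_s=150.0, bin_size=0.03,
                         base_rate=0.15, coupling=0.4, delay_bins=1, seed=9)
    return binarize(gen_coupled(spec), 0.03)


def random_stationary_model(rng, n, neuron_ids=None, rho=0.6):
    """Analytic second-order model of a random stable VAR(1) process."""
    from scipy.linalg import solve_discrete_lyapunov

    a = rng.normal(size=(n, n))
    a *= rho / max(abs(np.linalg.eigvals(a)))
    q_root = rng.normal(size=(n, n))
    q = q_root @ q_root.T / n + 0.5 * np.eye(n)
    sigma = solve_discrete_lyapunov(a, q)
    sigma = (sigma + sigma.T) / 2.0
    covlag = sigma @ a.T  # Cov(X_t, X_{t+1}) for X_{t+1} = A X_t + eps
    if neuron_ids is None:
        neuron_ids = tuple(str(i) for i in range(n))
    return GaussianModel(cov0=sigma, covlag=covlag, lag_bins=1,
                         n_samples=10 ** 6, neuron_ids=neuron_ids), a, q
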