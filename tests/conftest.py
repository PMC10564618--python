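import numpy as np
import pytest

from mudcod.netsim import SimulationConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """An easy, well-separated instance: 3 subjects x 2 times, 90 nodes, K=3."""
    config = SimulationConfig(
        n_nodes=90, n_communities=3, n_subjects=3, n_times=2,
        p_in=(0.35, 0.45), p_out=(0.05, 0.05), r_time=0.0, r_subject=0.0,
        setting="SSoS", seed=42,
    )
    networks, truth = generate(config)
    return config, networks, truth


def random_projection_grid(rng, G, S, T, k):
    """Random rank-k projection bases via QR of Gaussian matrices."""
    bases = [
        [np.linalg.qr(rng.standard_normal((G, k)))[0] for _ in range(T)]
        for _ in range(S)
    ]
    from mudcod.smoothing import ProjectionGrid

    return ProjectionGrid(bases, np.full((S, T), k, dtype=int))
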