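import numpy as np
import pytest

from tissuemix import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-tissue dataset with clear signal, reused across tests."""
    cfg = SimConfig(n=2000, m=(40, 40), h2=(0.5, 0.5), seed=202)
    Y, truth, blocks = simulate_dataset(cfg)
    return Y, truth, blocks


def random_mixture(rng, n=6, m=(2, 3), K=None):
    """A random, well-scaled mixture instance for oracle comparisons."""
    from tissuemix import MixtureParams, TissueBlock, TissueParams

    K = K or len(m)
    w = rng.dirichlet(np.ones(K))
    blocks, tissues = [], []
    for k in range(K):
        X = rng.standard_normal((n, m[k]))
        X = (X - X.mean(0)) / X.std(0)
        blocks.append(TissueBlock(f"t{k}", [f"t{k}s{j}" for j in range(m[k])], X))
        tissues.append(TissueParams(
            w=float(w[k]), alpha=float(rng.normal()),
            beta=rng.normal(0, 0.5, size=m[k]),
            sigma2_x=float(rng.uniform(0.1, 1.0)),
            sigma2_eps=float(rng.uniform(0.5, 2.0))))
    Y = rng.normal(0, 1.5, size=n)
    return Y, blocks, MixtureParams(tissues=tissues)
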