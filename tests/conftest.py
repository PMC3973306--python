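import numpy as np
import pandas as pd
import pytest

from crossmeth import BetaMatrix, SyntheticConfig, generate_pair


def make_beta(values, samples=None, probes=None) -> BetaMatrix:
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"S{i + 1}" for i in range(arr.shape[0])]
    probes = probes or [f"cg{j + 1:05d}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=samples, columns=probes))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_pair():
    """A compact synthetic study shared by tests that only need structure."""
    cfg = SyntheticConfig(n_samples=20, n_probes=120, seed=11)
    return generate_pair(cfg)
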