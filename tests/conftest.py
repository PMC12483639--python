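import numpy as np
import pytest

from oncodyn import GrowthParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fig3_erm1():
    """The step-like threshold parameterization: nu=1, r=0.12, A=1, K=1e4."""
    return GrowthParams.erm1_from_thresholds(1.0, 0.12, 1.0, 1e4)


def random_erm1_sets(n: int, seed: int = 0):
    """Random valid ERM1 parameter sets with a genuine threshold 0 < A < K."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        nu = 10.0 ** rng.uniform(-0.3, 1.5)
        r = 10.0 ** rng.uniform(-2, 0)
        A = 10.0 ** rng.uniform(0, 3)
        K = A * 10.0 ** rng.uniform(0.5, 5)
        out.append(GrowthParams.erm1_from_thresholds(nu, r, A, K))
    return out


def random_erm2_sets(n: int, seed: int = 0, nu_min: float = 1.0):
    """Random constant-s ERM2 sets built from (nu, r, A, K) targets."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        nu = 10.0 ** rng.uniform(np.log10(nu_min), 1.5)
        r = 10.0 ** rng.uniform(-2, 0)
        A = 10.0 ** rng.uniform(0.5, 3)
        K = A * 10.0 ** rng.uniform(1, 5)
        out.append(GrowthParams.erm2_from_thresholds(nu, r, A, K))
    return out
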