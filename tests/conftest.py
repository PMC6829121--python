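import numpy as np
import pytest

import mtcv
from mtcv.relatedness import GRM


@pytest.fixture(scope="session")
def tiny_grm() -> GRM:
    """60 lines in 6 families; enough structure for fast end-to-end tests."""
    return mtcv.simulate_breeding_grm(60, 6, 300, seed=42)


@pytest.fixture(scope="session")
def mid_grm() -> GRM:
    """200 lines in 20 families; used for Monte-Carlo checks."""
    return mtcv.simulate_breeding_grm(200, 20, 1000, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_random_grm(n: int, rng: np.random.Generator, ids=None) -> GRM:
    """A well-conditioned random PD relationship matrix with unit diagonal."""
    A = rng.standard_normal((n, 2 * n))
    K = A @ A.T / (2 * n) + 0.3 * np.eye(n)
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    if ids is None:
        ids = tuple(f"i{j}" for j in range(n))
    return GRM(ids=tuple(ids), values=K)
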