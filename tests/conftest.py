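import numpy as np
import pytest

from twt.corr import SnpCorrMatrix, TraitCorrMatrix
from twt.simulate import ar1_correlation, default_trait_correlation


@pytest.fixture
def rng():
    return np.random.default_rng(20230407)


@pytest.fixture
def trait_corr_q3():
    return TraitCorrMatrix(["t1", "t2", "t3"], ar1_correlation(0.5, 3))


@pytest.fixture
def snp_corr_m4():
    return SnpCorrMatrix(["s1", "s2", "s3", "s4"], ar1_correlation(0.6, 4))


@pytest.fixture(scope="session")
def realistic_pair():
    """The q=6 / m=9 covariance pair used by the larger statistical checks."""
    trait = TraitCorrMatrix(
        [f"trait{j}" for j in range(1, 7)], default_trait_correlation()
    )
    snp = SnpCorrMatrix([f"snp{k}" for k in range(1, 10)], ar1_correlation(0.8, 9))
    return snp, trait


def random_correlation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """A well-conditioned random correlation matrix (for property tests)."""
    a = rng.standard_normal((dim, dim + 5))
    cov = a @ a.T + dim * np.eye(dim)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
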