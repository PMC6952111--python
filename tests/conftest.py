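import numpy as np
import pytest

from aimfine import CausalPrior, simulate_haplotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """20-variant, 400-sample panel with two LD blocks, shared across tests."""
    return simulate_haplotypes(
        20, 400, [(0, 10, 0.8), (10, 20, 0.8)], maf_range=(0.2, 0.5), seed=99
    )


@pytest.fixture
def desk_prior():
    return CausalPrior(k_max=3)


def random_psd_correlation(rng, m, n_rows=None):
    """Random empirical correlation matrix (PSD, possibly near-singular)."""
    n_rows = n_rows or max(m + 5, 12)
    A = rng.standard_normal((n_rows, m))
    C = np.corrcoef(A.T)
    return (C + C.T) / 2.0
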