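import numpy as np
import pytest

from recqcycle import default_rates


@pytest.fixture(scope="session")
def bound_rates():
    return default_rates("dna_bound")


@pytest.fixture(scope="session")
def free_rates():
    return default_rates("dna_free")


@pytest.fixture(scope="session")
def md_bound_rates():
    return default_rates("dna_bound", "md_analog")


@pytest.fixture(scope="session")
def md_free_rates():
    return default_rates("dna_free", "md_analog")


def expm_stationary(rates, atp, adp=0.0, pi=0.0, t_long=None):
    """Independent stationary-state oracle: propagate the pseudo-first-order
    master equation to long times with the matrix exponential."""
    from scipy.linalg import expm

    from recqcycle.scheme import rate_matrix

    Q = rate_matrix(rates, atp, adp, pi)
    A = Q.T - np.diag(Q.sum(axis=1))
    rates_nz = Q[Q > 0]
    if t_long is None:
        t_long = 200.0 / rates_nz.min()
    p = expm(A * t_long) @ np.array([1.0, 0.0, 0.0, 0.0])
    return p / p.sum()
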