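import numpy as np
import pytest

from citecca import sim, io_prep


@pytest.fixture(scope="session")
def easy_pair():
    """Small, strongly separated 4-cluster data set (fast to fit)."""
    cfg = sim.SimConfig(
        n_clusters=4, cells_per_cluster=60, n_genes=200, n_proteins=40,
        de_prob_rna=0.5, de_prob_protein=0.9, de_factor_location=2.0, seed=7,
    )
    return sim.simulate_cite(cfg)


@pytest.fixture(scope="session")
def easy_prep(easy_pair):
    return io_prep.preprocess(easy_pair)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def finite_difference_grad(f, x0, eps=1e-6):
    """Central finite-difference gradient of a scalar-valued f at x0."""
    from citecca._autodiff import Tensor

    num = np.zeros_like(x0, dtype=float)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x0.copy(), x0.copy()
        xp[i] += eps
        xm[i] -= eps
        num[i] = (float(f(Tensor(xp)).data) - float(f(Tensor(xm)).data)) / (2 * eps)
    return num


def autodiff_grad(f, x0):
    from citecca._autodiff import Parameter

    x = Parameter(x0.copy())
    f(x).backward()
    return x.grad
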