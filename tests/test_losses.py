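"""Loss oracles: closed-form count likelihoods, an independent classical-CCA
eigen-solve, brute-force Cauchy-Schwarz divergence sums, and
finite-difference gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg as sla
from scipy import stats

from citecca import losses
from citecca._autodiff import Tensor

from conftest import autodiff_grad, finite_difference_grad


# ---------------------------------------------------------------------------
# NB / ZINB likelihoods
# ---------------------------------------------------------------------------

def _nb_logpmf(x, mu, theta):
    # scipy parameterisation: n = theta, p = theta / (theta + mu)
    return stats.nbinom.logpmf(x, theta, theta / (theta + mu))


def test_nb_nll_geometric_closed_form():
    # theta=1 is geometric: pmf(3 | mu=2) = (1/3)(2/3)^3 = 8/81
    val = losses.nb_nll(np.array([[3.0]]), np.array([[2.0]]), np.array([[1.0]]))
    assert val.item() == pytest.approx(-np.log(8 / 81), abs=1e-10)


def test_nb_nll_zero_count_tiny_mean_is_zero():
    val = losses.nb_nll(np.array([[0.0]]), np.array([[1e-12]]), np.array([[1.0]]))
    assert val.item() == pytest.approx(0.0, abs=1e-9)


def test_nb_pmf_normalizes():
    mu, theta = 1.5, 2.0
    x = np.arange(201, dtype=float)[None, :]
    nll_each = [losses.nb_nll(np.array([[xi]]), np.array([[mu]]),
                              np.array([[theta]])).item() for xi in x.ravel()]
    assert np.exp(-np.array(nll_each)).sum() == pytest.approx(1.0, abs=1e-8)


def test_nb_nll_matches_scipy_on_grid():
    xs = np.arange(0, 51, 5, dtype=float)
    mus = np.array([0.1, 1.0, 5.0, 20.0])
    thetas = np.array([0.1, 1.0, 10.0])
    for mu in mus:
        for theta in thetas:
            ours = np.array([
                losses.nb_nll(np.array([[x]]), np.array([[mu]]),
                              np.array([[theta]])).item() for x in xs])
            ref = -_nb_logpmf(xs, mu, theta)
            np.testing.assert_allclose(ours, ref, atol=1e-6)


def test_zinb_equals_nb_when_pi_zero(rng):
    x = rng.poisson(3.0, size=(5, 7)).astype(float)
    mu = rng.uniform(0.5, 5.0, size=(5, 7))
    theta = rng.uniform(0.5, 5.0, size=(5, 7))
    a = losses.zinb_nll(x, mu, theta, np.zeros_like(mu))
    b = losses.nb_nll(x, mu, theta)
    assert a.item() == pytest.approx(b.item(), abs=1e-7)


def test_zinb_point_mass_at_zero():
    val = losses.zinb_nll(np.array([[0.0]]), np.array([[2.0]]),
                          np.array([[1.0]]), np.array([[1.0]]))
    assert val.item() == pytest.approx(0.0, abs=1e-9)


def test_zinb_mixture_closed_form():
    # pmf(0) = 0.5 + 0.5 * NB(0 | mu=2, theta=1) = 0.5 + 0.5/3 = 2/3
    val = losses.zinb_nll(np.array([[0.0]]), np.array([[2.0]]),
                          np.array([[1.0]]), np.array([[0.5]]))
    assert val.item() == pytest.approx(np.log(1.5), abs=1e-9)


@settings(deadline=None, max_examples=30)
@given(
    x=st.integers(min_value=0, max_value=50),
    mu=st.floats(min_value=0.1, max_value=20.0),
    theta=st.floats(min_value=0.1, max_value=10.0),
    pi=st.floats(min_value=0.0, max_value=0.9),
)
def test_zinb_matches_direct_mixture_evaluation(x, mu, theta, pi):
    ours = losses.zinb_nll(np.array([[float(x)]]), np.array([[mu]]),
                           np.array([[theta]]), np.array([[pi]])).item()
    nb = np.exp(_nb_logpmf(x, mu, theta))
    direct = pi * (x == 0) + (1.0 - pi) * nb
    assert ours == pytest.approx(-np.log(direct), abs=1e-6)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        losses.nb_nll(np.array([[-1.0]]), np.array([[1.0]]), np.array([[1.0]]))


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def _classical_cca_corrsum(hr, hp, r1, r2, top_k=None):
    """Independent oracle: canonical correlations through the SVD of
    S11^{-1/2} S12 S22^{-1/2} computed with scipy matrix functions."""
    n = hr.shape[1]
    hrc = hr - hr.mean(axis=1, keepdims=True)
    hpc = hp - hp.mean(axis=1, keepdims=True)
    s11 = hrc @ hrc.T / (n - 1) + r1 * np.eye(hr.shape[0])
    s22 = hpc @ hpc.T / (n - 1) + r2 * np.eye(hp.shape[0])
    s12 = hrc @ hpc.T / (n - 1)
    t = (sla.fractional_matrix_power(s11, -0.5) @ s12
         @ sla.fractional_matrix_power(s22, -0.5))
    sv = np.linalg.svd(t, compute_uv=False)
    return np.sort(sv)[::-1][:top_k].sum() if top_k else sv.sum()


def test_self_correlation_is_dimension(rng):
    h = rng.normal(size=(4, 100))
    val = losses.cca_loss(h, h, 1e-9, 1e-9).item()
    assert val == pytest.approx(4.0, abs=1e-4)


def test_independent_noise_has_low_correlation(rng):
    hr = rng.normal(size=(4, 2000))
    hp = rng.normal(size=(4, 2000))
    val = losses.cca_loss(hr, hp, 1e-4, 1e-4).item()
    assert val < 0.3
    assert val == pytest.approx(
        _classical_cca_corrsum(hr, hp, 1e-4, 1e-4), abs=1e-6)


def test_toy_matrices_match_eigen_solve_oracle(rng):
    hr = rng.normal(size=(2, 6))
    hp = 0.3 * hr + rng.normal(size=(2, 6))
    for top_k in (None, 1):
        ours = losses.cca_loss(hr, hp, 1e-3, 1e-3, top_k=top_k).item()
        ref = _classical_cca_corrsum(hr, hp, 1e-3, 1e-3, top_k=top_k)
        assert ours == pytest.approx(ref, abs=1e-6)


def test_invariance_under_invertible_linear_maps(rng):
    hr = rng.normal(size=(3, 80))
    hp = rng.normal(size=(3, 80)) + 0.5 * hr
    base = losses.cca_loss(hr, hp, 1e-9, 1e-9).item()
    m1 = rng.normal(size=(3, 3)) + 2 * np.eye(3)
    m2 = rng.normal(size=(3, 3)) + 2 * np.eye(3)
    mapped = losses.cca_loss(m1 @ hr, m2 @ hp, 1e-9, 1e-9).item()
    assert mapped == pytest.approx(base, abs=1e-4)


def test_cca_input_validation(rng):
    h = rng.normal(size=(3, 1))
    with pytest.raises(ValueError):
        losses.cca_loss(h, h)
    h = rng.normal(size=(3, 10))
    with pytest.raises(ValueError):
        losses.cca_loss(h, h, r1=0.0)


# ---------------------------------------------------------------------------
# Gaussian kernel
# ---------------------------------------------------------------------------

def test_kernel_unit_diagonal_and_symmetry(rng):
    k = losses.gaussian_kernel(rng.normal(size=(10, 3)))
    np.testing.assert_allclose(np.diag(k.data), 1.0, atol=1e-12)
    np.testing.assert_allclose(k.data, k.data.T, atol=1e-12)
    assert np.all(k.data > 0) and np.all(k.data <= 1.0 + 1e-12)


def test_kernel_closed_form_at_distance_sigma_sqrt2():
    h = np.array([[0.0], [2.0]])
    k = losses.gaussian_kernel(h, sigma=2.0 / np.sqrt(2.0))
    assert k.data[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)


def test_kernel_matches_pairwise_oracle(rng):
    h = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
    sigma = 1.3
    k = losses.gaussian_kernel(h, sigma=sigma).data
    for i in range(4):
        for j in range(4):
            d2 = np.sum((h[i] - h[j]) ** 2)
            assert k[i, j] == pytest.approx(np.exp(-d2 / (2 * sigma**2)), abs=1e-12)


def test_kernel_identical_rows_warns():
    with pytest.warns(UserWarning, match="identical"):
        losses.gaussian_kernel(np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# CS-divergence clustering terms
# ---------------------------------------------------------------------------

def _brute_cs(cols, kernel):
    k = cols.shape[1]
    total = 0.0
    for i in range(k - 1):
        for j in range(i + 1, k):
            num = cols[:, i] @ kernel @ cols[:, j]
            den = np.sqrt((cols[:, i] @ kernel @ cols[:, i])
                          * (cols[:, j] @ kernel @ cols[:, j]))
            total += num / den
    return total / k


def test_l1_zero_for_block_kernel_and_aligned_hard_labels():
    a = np.repeat(np.eye(2), 3, axis=0)  # 6 cells, hard assignments
    kernel = sla.block_diag(np.ones((3, 3)), np.ones((3, 3)))
    assert losses.l1_separability(a, kernel).item() == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("k", [2, 3, 5])
def test_uniform_assignments_hit_upper_bound(k, rng):
    a = np.full((12, k), 1.0 / k)
    kernel = losses.gaussian_kernel(rng.normal(size=(12, 3)))
    bound = (k - 1) / 2.0
    assert losses.l1_separability(a, kernel).item() == pytest.approx(bound, rel=1e-10)
    assert losses.l2_simplex(a, kernel).item() == pytest.approx(bound, rel=1e-10)


def test_l1_l2_match_brute_force(rng):
    logits = rng.normal(size=(7, 3))
    a = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    kernel = losses.gaussian_kernel(rng.normal(size=(7, 4))).data
    assert losses.l1_separability(a, kernel).item() == pytest.approx(
        _brute_cs(a, kernel), abs=1e-10)
    m = np.exp(-np.linalg.norm(a[:, None, :] - np.eye(3)[None, :, :], axis=2))
    assert losses.l2_simplex(a, kernel).item() == pytest.approx(
        _brute_cs(m, kernel), abs=1e-6)


def test_l2_hard_assignment_corner_values():
    a = np.repeat(np.eye(2), 2, axis=0)
    kernel = np.eye(4)
    # m peaks at 1 on own-cluster cells and e^{-sqrt(2)} elsewhere
    m = np.exp(-np.linalg.norm(a[:, None, :] - np.eye(2)[None, :, :], axis=2))
    assert m[0, 0] == pytest.approx(1.0)
    assert m[0, 1] == pytest.approx(np.exp(-np.sqrt(2.0)))
    val = losses.l2_simplex(a, kernel).item()
    assert val == pytest.approx(_brute_cs(m, kernel), abs=1e-6)


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=2, max_value=5), st.integers(min_value=0, max_value=10**6))
def test_l1_l2_bounded_by_cauchy_schwarz(k, seed):
    rng = np.random.default_rng(seed)
    logits = rng.normal(size=(10, k))
    a = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    kernel = losses.gaussian_kernel(rng.normal(size=(10, 3)))
    bound = (k - 1) / 2.0 + 1e-9
    assert 0.0 <= losses.l1_separability(a, kernel).item() <= bound
    assert 0.0 <= losses.l2_simplex(a, kernel).item() <= bound


def test_l3_orthogonal_one_hot_is_zero():
    a = np.repeat(np.eye(3), 2, axis=0)
    assert losses.l3_orthogonality(a).item() == pytest.approx(0.0)


def test_l3_uniform_closed_form():
    n = 8
    a = np.full((n, 2), 0.5)
    assert losses.l3_orthogonality(a, normalize=False).item() == pytest.approx(n / 4)
    assert losses.l3_orthogonality(a).item() == pytest.approx(0.25)


def test_l3_matches_double_loop(rng):
    a = rng.dirichlet(np.ones(3), size=5)
    expected = sum(a[:, i] @ a[:, j] for i in range(3) for j in range(i + 1, 3))
    assert losses.l3_orthogonality(a, normalize=False).item() == pytest.approx(expected)


# ---------------------------------------------------------------------------
# gradients and combination
# ---------------------------------------------------------------------------

def test_cluster_losses_gradient_check_on_six_cell_fixture(rng):
    h0 = rng.normal(size=(6, 3))
    logits0 = rng.normal(size=(6, 2))
    kernel_const = losses.gaussian_kernel(h0).data

    def f_l1(t):
        return losses.l1_separability(t.softmax(axis=1), Tensor(kernel_const))

    def f_l2(t):
        return losses.l2_simplex(t.softmax(axis=1), Tensor(kernel_const))

    def f_l3(t):
        return losses.l3_orthogonality(t.softmax(axis=1))

    def f_kernel(t):
        a_const = Tensor(np.exp(logits0) / np.exp(logits0).sum(1, keepdims=True))
        return losses.l1_separability(a_const, losses.gaussian_kernel(t, sigma=1.0))

    for f, x0 in [(f_l1, logits0), (f_l2, logits0), (f_l3, logits0), (f_kernel, h0)]:
        g = autodiff_grad(f, x0)
        num = finite_difference_grad(f, x0)
        np.testing.assert_allclose(g, num, atol=1e-4, rtol=1e-4)


def test_nll_gradient_check(rng):
    x = rng.poisson(2.0, size=(4, 3)).astype(float)

    def f_nb(t):
        return losses.nb_nll(x, t.exp(), Tensor(np.full((4, 3), 2.0)))

    def f_zinb(t):
        return losses.zinb_nll(x, t.exp(), Tensor(np.full((4, 3), 2.0)),
                               Tensor(np.full((4, 3), 0.3)))

    x0 = rng.normal(size=(4, 3))
    for f in (f_nb, f_zinb):
        np.testing.assert_allclose(autodiff_grad(f, x0),
                                   finite_difference_grad(f, x0),
                                   atol=1e-4, rtol=1e-4)


def test_total_loss_weighted_sum():
    comps = [Tensor(np.array(v)) for v in (10.0, 3.0, 0.5, 0.7, 0.2)]
    total, br = losses.total_loss(*comps, gamma=2.0, delta=0.5)
    assert total.item() == pytest.approx(2.0 * 10.0 - 0.5 * 3.0 + 1.4)
    assert br.total == pytest.approx(br.gamma * br.l_ae - br.delta * br.l_cca
                                     + br.l1 + br.l2 + br.l3)


def test_total_loss_masking():
    comps = [Tensor(np.array(v)) for v in (10.0, 3.0, 0.5, 0.7, 0.2)]
    total, _ = losses.total_loss(*comps, gamma=0.0, delta=0.0)
    assert total.item() == pytest.approx(1.4)
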