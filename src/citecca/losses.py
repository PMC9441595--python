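"""Training objectives.

Four families of terms, all differentiable through :mod:`citecca._autodiff`:

* ``nb_nll`` / ``zinb_nll`` — negative log-likelihood of the raw counts under
  a negative binomial, optionally zero-inflated with dropout weight pi.
* ``cca_loss`` — the total canonical correlation between the two omics
  latents: the trace (nuclear) norm of T = S11^{-1/2} S12 S22^{-1/2} built
  from regularised covariance estimates.  Larger is better; the trainer
  subtracts it from the minimised total.
* ``gaussian_kernel`` + ``l1_separability`` / ``l2_simplex`` /
  ``l3_orthogonality`` — the Cauchy-Schwarz divergence clustering terms:
  L1 drives kernel-weighted separation between soft clusters, L2 pulls each
  cell's assignment vector toward a simplex corner, L3 pushes assignment
  vectors of different cells toward orthogonality.
* ``total_loss`` — gamma * L_AE - delta * L_cca + (L1 + L2 + L3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, eigh

__all__ = [
    "LossBreakdown",
    "nb_nll",
    "zinb_nll",
    "cca_loss",
    "gaussian_kernel",
    "l1_separability",
    "l2_simplex",
    "l3_orthogonality",
    "total_loss",
]

_EIG_FLOOR = 1e-12


@dataclass
class LossBreakdown:
    """All loss components of one step/epoch.  ``l_cca`` is the positive
    total correlation (the trainer maximises it); ``total`` is the minimised
    objective gamma*l_ae - delta*l_cca + l1 + l2 + l3."""

    l_ae: float
    l_cca: float
    l1: float
    l2: float
    l3: float
    total: float
    gamma: float
    delta: float

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("l_ae", "l_cca", "l1", "l2", "l3", "total", "gamma", "delta")}


# ---------------------------------------------------------------------------
# count likelihoods
# ---------------------------------------------------------------------------

def nb_nll(x, mu, theta) -> Tensor:
    """Mean over cells of the summed-over-features NB negative log-likelihood.

    NB(x | mu, theta) = G(x+theta) / (G(x+1) G(theta)) *
                        (theta/(theta+mu))^theta * (mu/(theta+mu))^x
    evaluated through log-gamma for numerical stability.
    """
    x = as_tensor(np.asarray(x if not isinstance(x, Tensor) else x.data, dtype=float))
    if np.any(x.data < 0):
        raise ValueError("counts must be non-negative")
    mu, theta = as_tensor(mu), as_tensor(theta)
    log_theta_mu = (theta + mu).log()
    ll = (
        (x + theta).lgamma() - (x + 1.0).lgamma() - theta.lgamma()
        + theta * (theta.log() - log_theta_mu)
        + x * (mu.log() - log_theta_mu)
    )
    return -(ll.sum(axis=1).mean() if x.ndim == 2 else ll.sum())


def zinb_nll(x, mu, theta, pi) -> Tensor:
    """ZINB negative log-likelihood; the zero-inflation mass applies at x=0.

    ZINB(x) = pi * 1{x=0} + (1-pi) * NB(x); at x=0 the two branches are
    combined in log space (log-sum-exp style) for stability.
    """
    xa = np.asarray(x if not isinstance(x, Tensor) else x.data, dtype=float)
    if np.any(xa < 0):
        raise ValueError("counts must be non-negative")
    x = as_tensor(xa)
    mu, theta, pi = as_tensor(mu), as_tensor(theta), as_tensor(pi)
    log_theta_mu = (theta + mu).log()
    nb_ll = (
        (x + theta).lgamma() - (x + 1.0).lgamma() - theta.lgamma()
        + theta * (theta.log() - log_theta_mu)
        + x * (mu.log() - log_theta_mu)
    )
    # at x=0: log(pi + (1-pi) * NB(0)); NB(0) = (theta/(theta+mu))^theta
    nb0_ll = theta * (theta.log() - log_theta_mu)
    zero_ll = (pi + (1.0 - pi) * nb0_ll.exp() + 1e-12).log()
    nonzero_ll = (1.0 - pi + 1e-12).log() + nb_ll
    is_zero = (xa == 0).astype(float)
    ll = zero_ll * is_zero + nonzero_ll * (1.0 - is_zero)
    return -(ll.sum(axis=1).mean() if x.ndim == 2 else ll.sum())


# ---------------------------------------------------------------------------
# canonical correlation
# ---------------------------------------------------------------------------

def _inv_sqrtm(s: Tensor) -> Tensor:
    """Inverse matrix square root of a symmetric positive-definite matrix."""
    w, v = eigh(s)
    w = w.clip(lo=_EIG_FLOOR)
    return v @ (v * (w ** -0.5)).T


def cca_loss(h_r, h_p, r1: float = 1e-3, r2: float = 1e-3,
             top_k: int | None = None) -> Tensor:
    """Total canonical correlation between two d x n latent views.

    Rows are features (latent dimensions), columns are cells.  Covariances
    are estimated with ridge regularisers r1, r2; the value is the sum of
    the ``top_k`` largest singular values of T = S11^{-1/2} S12 S22^{-1/2}
    (all of them when ``top_k`` is None), computed as tr((T'T)^{1/2}).
    """
    h_r, h_p = as_tensor(h_r), as_tensor(h_p)
    d1, n = h_r.shape
    d2, n2 = h_p.shape
    if n != n2:
        raise ValueError("views must share the sample dimension")
    if n < 2:
        raise ValueError("CCA needs at least 2 samples")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("regularizers must be positive")
    hbar_r = h_r - h_r.mean(axis=1, keepdims=True)
    hbar_p = h_p - h_p.mean(axis=1, keepdims=True)
    c = 1.0 / (n - 1)
    s11 = (hbar_r @ hbar_r.T) * c + Tensor(r1 * np.eye(d1))
    s22 = (hbar_p @ hbar_p.T) * c + Tensor(r2 * np.eye(d2))
    s12 = (hbar_r @ hbar_p.T) * c
    t = _inv_sqrtm(s11) @ s12 @ _inv_sqrtm(s22)
    w, _ = eigh(t.T @ t)  # eigenvalues ascending = squared singular values
    sv = w.clip(lo=_EIG_FLOOR).sqrt()
    if top_k is not None:
        k = min(int(top_k), sv.shape[0])
        sv = sv[sv.shape[0] - k:]
    return sv.sum()


# ---------------------------------------------------------------------------
# Cauchy-Schwarz divergence clustering
# ---------------------------------------------------------------------------

def gaussian_kernel(h, sigma_rel: float = 0.15, sigma: float | None = None) -> Tensor:
    """Gaussian similarity kernel exp(-||h_i - h_j||^2 / (2 sigma^2)).

    The bandwidth is relative: sigma = sigma_rel * median pairwise distance,
    recomputed from the current batch without gradient flow through sigma.
    An absolute ``sigma`` overrides the relative rule.
    """
    h = as_tensor(h)
    n = h.shape[0]
    if n < 2:
        raise ValueError("kernel needs at least 2 points")
    sq = (h * h).sum(axis=1, keepdims=True)
    d2 = (sq + sq.T - 2.0 * (h @ h.T)).clip(lo=0.0)
    if sigma is None:
        dists = np.sqrt(d2.data[np.triu_indices(n, k=1)])
        med = float(np.median(dists))
        if med <= 0:
            warnings.warn("all kernel inputs identical; using floor bandwidth")
            med = 1e-6
        sigma = max(sigma_rel * med, 1e-6)
    k = (d2 * (-1.0 / (2.0 * sigma**2))).exp()
    return k


def _cs_divergence_columns(cols: Tensor, kernel: Tensor) -> Tensor:
    """(1/k) * sum_{i<j} c_i'K c_j / sqrt(c_i'K c_i * c_j'K c_j) over column
    pairs of ``cols`` — the sample-based Cauchy-Schwarz divergence estimator
    shared by L1 and L2."""
    k = cols.shape[1]
    quad = cols.T @ kernel @ cols  # k x k matrix of all quadratic forms
    diag = np.diag(quad.data)
    if np.any(diag <= 0):
        warnings.warn("cluster with zero soft mass; skipping degenerate pairs")
    total = Tensor(0.0)
    for i in range(k - 1):
        for j in range(i + 1, k):
            denom_val = diag[i] * diag[j]
            if denom_val <= 0:
                continue
            total = total + quad[i, j] / (quad[i, i] * quad[j, j]).sqrt()
    return total / k


def l1_separability(assignments, kernel) -> Tensor:
    """Cluster separability/compactness: CS divergence over the columns of
    the soft assignment matrix under the Gaussian kernel.  In [0, (K-1)/2]."""
    return _cs_divergence_columns(as_tensor(assignments), as_tensor(kernel))


def l2_simplex(assignments, kernel) -> Tensor:
    """Simplex-corner closeness: build m_{a,j} = exp(-||alpha_a - e_j||)
    (unsquared Euclidean distance to corner j) and apply the same CS
    divergence functional to m's columns."""
    a = as_tensor(assignments)
    n, k = a.shape
    eye = np.eye(k)
    cols = []
    for j in range(k):
        diff = a - Tensor(eye[j][None, :])
        dist = ((diff * diff).sum(axis=1) + 1e-12).sqrt()
        cols.append((-dist).exp())
    m_data = np.stack([c.data for c in cols], axis=1)
    m = Tensor(m_data, parents=tuple(cols))
    if m.requires_grad:
        def bw(g):
            for j, c in enumerate(cols):
                if c.requires_grad:
                    c._accumulate(g[:, j])
        m._backward = bw
    return _cs_divergence_columns(m, as_tensor(kernel))


def l3_orthogonality(assignments, normalize: bool = True) -> Tensor:
    """Sum of the strictly upper-triangular entries of A'A (divided by n by
    default, so the value is batch-size free)."""
    a = as_tensor(assignments)
    n, k = a.shape
    gram = a.T @ a
    upper = gram * Tensor(np.triu(np.ones((k, k)), k=1))
    s = upper.sum()
    return s / n if normalize else s


def total_loss(l_ae: Tensor, l_cca: Tensor, l1: Tensor, l2: Tensor, l3: Tensor,
               gamma: float, delta: float) -> tuple[Tensor, LossBreakdown]:
    """Combine components; correlation enters negatively (it is maximised)."""
    total = gamma * l_ae - delta * l_cca + (l1 + l2 + l3)
    breakdown = LossBreakdown(
        l_ae=float(l_ae.data), l_cca=float(l_cca.data), l1=float(l1.data),
        l2=float(l2.data), l3=float(l3.data), total=float(total.data),
        gamma=gamma, delta=delta,
    )
    return total, breakdown
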