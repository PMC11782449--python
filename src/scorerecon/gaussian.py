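"""Analytic Gaussian prior: the exact-score oracle for sampler validation.

A multivariate normal N(mu, Sigma) over flattened small images has a
closed-form score at every perturbation level — the sigma-smoothed density
is N(mu, Sigma + sigma^2 I) with score

    grad_x log p_sigma(x) = -(Sigma + sigma^2 I)^{-1} (x - mu),

and, for a noiseless linear measurement y = A x, a closed-form conditional
mean

    E[x | A x = y] = mu + Sigma A^T (A Sigma A^T)^+ (y - A mu).

These exact quantities let the annealed Langevin sampler and the
measurement-consistent reconstruction be checked against ground truth
without any trained network in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kspace import SamplingMask, forward_fourier

__all__ = [
    "GaussianPrior",
    "analytic_gaussian_score",
    "masked_fourier_matrix",
    "gaussian_posterior_mean",
]


@dataclass(frozen=True)
class GaussianPrior:
    """N(mu, Sigma) over flattened images; Sigma must be symmetric positive-definite."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mean, dtype=float).ravel()
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "covariance", cov)
        if cov.shape != (mu.size, mu.size):
            raise ValueError("covariance shape must match mean dimension")
        if np.max(np.abs(cov - cov.T)) > 1e-10:
            raise ValueError("covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(cov)[0]
        if eigmin <= 0:
            raise ValueError(f"covariance must be positive-definite (eigmin={eigmin})")

    @property
    def dim(self) -> int:
        return self.mean.size


def analytic_gaussian_score(
    prior: GaussianPrior, x: np.ndarray, sigma: float = 0.0
) -> np.ndarray:
    """Exact score of the sigma-perturbed Gaussian: -(Sigma + sigma^2 I)^{-1}(x - mu)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = np.asarray(x, dtype=float).ravel()
    cov = prior.covariance + sigma**2 * np.eye(prior.dim)
    return -np.linalg.solve(cov, x - prior.mean)


def masked_fourier_matrix(mask: SamplingMask, n_rows: int) -> np.ndarray:
    """Real matrix B of the masked centered Fourier operator.

    Maps a flattened real (n_rows x n_columns) image to the stacked real and
    imaginary parts of the kept k-space entries, so that
    ``B @ x.ravel() == concat(Re(y_kept), Im(y_kept))``.  Because the input
    is real and the spectrum Hermitian, B is generally rank-deficient; the
    posterior formula uses a pseudo-inverse.
    """
    n = n_rows * mask.n_columns
    kept = np.flatnonzero(mask.keep)
    m = n_rows * kept.size
    B = np.empty((2 * m, n))
    basis = np.zeros((n_rows, mask.n_columns))
    for j in range(n):
        basis.ravel()[j] = 1.0
        k = forward_fourier(basis)[:, kept].ravel()
        B[:m, j] = k.real
        B[m:, j] = k.imag
        basis.ravel()[j] = 0.0
    return B


def gaussian_posterior_mean(
    prior: GaussianPrior, B: np.ndarray, y_stacked: np.ndarray
) -> np.ndarray:
    """Closed-form E[x | B x = y] for a noiseless linear observation of N(mu, Sigma)."""
    mu, cov = prior.mean, prior.covariance
    G = B @ cov @ B.T
    resid = y_stacked - B @ mu
    return mu + cov @ B.T @ np.linalg.lstsq(G, resid, rcond=None)[0]
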