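"""Entropy estimators and their exact gradients.

Two kinds of entropy drive the correspondence optimization:

* configuration-space (sampling) entropy of the particles on one surface,
  estimated with an isotropic Gaussian Parzen kernel — maximizing it spreads
  particles uniformly over the surface;
* subspace (shape-space) entropy ``1/2 * sum_i log(lambda_i + alpha)`` of a
  mean-centered data matrix, where ``lambda_i`` are the eigenvalues of the
  sample covariance — minimizing it makes the statistical model compact.

All gradients here are the exact derivatives of the returned estimates (the
kernel widths and the regularization are treated as lagged constants), so
they can be validated against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "parzen_sigmas",
    "sampling_entropy",
    "subspace_entropy",
    "correspondence_gradient",
    "center_columns",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def parzen_sigmas(points: np.ndarray, floor: float, k_neighbors: int = 6) -> np.ndarray:
    """Per-particle kernel widths: median distance to the ``k_neighbors``
    nearest other particles, floored at ``floor`` (mm)."""
    points = np.asarray(points, dtype=float)
    m = len(points)
    if m < 2:
        return np.full(m, max(floor, np.finfo(float).tiny))
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    k = min(k_neighbors, m - 1)
    nearest = np.sort(d, axis=1)[:, :k]
    sig = np.median(nearest, axis=1)
    return np.maximum(sig, floor)


def sampling_entropy(points: np.ndarray, sigmas: np.ndarray):
    """Parzen entropy estimate of one surface's particle configuration.

    ``H = -(1/M) sum_m log p(x_m)`` with
    ``p(x_m) = (1/(M-1)) sum_{j != m} N(x_m; x_j, sigma_j^2 I)``.

    Returns ``(H, grad)`` where ``grad[i] = dH/dx_i`` (the ascent direction
    on H, i.e. net inter-particle repulsion). For a single particle both are
    zero. Kernel widths are held fixed (lagged statistics).
    """
    points = np.asarray(points, dtype=float)
    m = len(points)
    if m < 2:
        return 0.0, np.zeros_like(points)
    sigmas = np.asarray(sigmas, dtype=float)
    diffs = points[:, None, :] - points[None, :, :]  # d[i, j] = x_i - x_j
    r2 = np.sum(diffs * diffs, axis=-1)
    s2 = sigmas**2
    # kernel centered at x_j evaluated at x_i, with x_j's width
    log_k = -0.5 * r2 / s2[None, :] - 1.5 * _LOG_2PI - 3.0 * np.log(sigmas)[None, :]
    kern = np.exp(log_k)
    np.fill_diagonal(kern, 0.0)
    p = kern.sum(axis=1) / (m - 1)
    p = np.maximum(p, np.finfo(float).tiny)
    h = -float(np.mean(np.log(p)))

    a = kern / s2[None, :]  # A[i, j] = K(x_i; x_j) / sigma_j^2
    b = a / p[:, None]
    grad = np.einsum("ij,ijc->ic", b + b.T, diffs) / (m * (m - 1))
    return h, grad


def center_columns(y: np.ndarray) -> np.ndarray:
    """Remove the across-sample (column) mean from a data matrix."""
    return y - y.mean(axis=1, keepdims=True)


def subspace_entropy(y: np.ndarray, alpha_reg: float) -> float:
    """``1/2 * sum_i log(lambda_i + alpha_reg)`` over ALL eigenvalues of the
    sample covariance ``Y Y^T / (N - 1)`` of the (already centered) D x N
    matrix ``y`` — including the D - rank structural zeros.

    Computed through whichever Gram matrix is smaller, so a dM x dM
    covariance is never materialized when dM > N.
    """
    y = np.asarray(y, dtype=float)
    d, n = y.shape
    if n < 2:
        raise ValueError("subspace entropy needs at least 2 samples")
    if alpha_reg <= 0:
        raise ValueError("alpha_reg must be positive")
    if d <= n:
        lam = np.linalg.eigvalsh(y @ y.T / (n - 1))
        lam = np.clip(lam, 0.0, None)
        return 0.5 * float(np.sum(np.log(lam + alpha_reg)))
    nu = np.linalg.eigvalsh(y.T @ y / (n - 1))
    nu = np.clip(nu, 0.0, None)
    return 0.5 * float(
        np.sum(np.log(nu + alpha_reg)) + (d - n) * np.log(alpha_reg)
    )


def correspondence_gradient(y: np.ndarray, alpha_reg: float) -> np.ndarray:
    """Exact gradient ``dH/dY`` of :func:`subspace_entropy` at ``y``.

    Algebraically ``Y (Y^T Y + alpha (N-1) I)^{-1}`` via the dual (N x N)
    system; one column per sample. The optimizer steps along the negative of
    this matrix to shrink the subspace entropy.
    """
    y = np.asarray(y, dtype=float)
    d, n = y.shape
    if n < 2:
        raise ValueError("correspondence gradient needs at least 2 samples")
    gram = y.T @ y / (n - 1) + alpha_reg * np.eye(n)
    return np.linalg.solve(gram, y.T).T / (n - 1)


def eigenvalue_scale(y: np.ndarray) -> float:
    """Mean positive covariance eigenvalue of a centered matrix (0 if the
    matrix is identically zero); sets the regularization scale."""
    y = np.asarray(y, dtype=float)
    d, n = y.shape
    if n < 2:
        return 0.0
    g = y.T @ y / (n - 1) if d > n else y @ y.T / (n - 1)
    lam = np.clip(np.linalg.eigvalsh(g), 0.0, None)
    rank = int(np.sum(lam > 1e-12 * max(lam.max(initial=0.0), 1e-300)))
    if rank == 0:
        return 0.0
    return float(lam.sum() / rank)
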