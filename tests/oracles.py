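"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit scalar loops and the most naive
formulas available, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_design(pixels: np.ndarray, order: int):
    """Enumerate the valid region pixel by pixel; no slicing tricks.

    Returns (y, X, offsets) with rows in column-major order over the valid
    region, matching the package's documented layout.
    """
    m, n = pixels.shape
    L = order
    offsets = [
        (di, dj)
        for di in range(L + 1)
        for dj in range(L + 1)
        if (di, dj) != (0, 0)
    ]
    y_list, x_rows = [], []
    for j in range(L, n):  # column-major: j outer
        for i in range(L, m):
            y_list.append(pixels[i, j])
            x_rows.append([pixels[i - di, j - dj] for di, dj in offsets])
    return np.array(y_list), np.array(x_rows), offsets


def brute_force_ols(y: np.ndarray, X: np.ndarray):
    """Normal equations, HC0 sandwich, and t-stats assembled term by term."""
    N, k = X.shape
    xtx = np.zeros((k, k))
    xty = np.zeros(k)
    for r in range(N):
        for a in range(k):
            xty[a] += X[r, a] * y[r]
            for b in range(k):
                xtx[a, b] += X[r, a] * X[r, b]
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    resid = np.array([y[r] - sum(X[r, a] * beta[a] for a in range(k)) for r in range(N)])
    meat = np.zeros((k, k))
    for r in range(N):
        e2 = resid[r] ** 2
        for a in range(k):
            for b in range(k):
                meat[a, b] += X[r, a] * X[r, b] * e2
    cov = xtx_inv @ meat @ xtx_inv
    t_stats = np.array([beta[a] / np.sqrt(cov[a, a]) for a in range(k)])
    return beta, cov, t_stats, resid


def scalar_lag_recursion(
    shape, beta, innovation_sd, boundary_mean, boundary_sd, seed
) -> np.ndarray:
    """Pixel-by-pixel forward recursion mirroring LagSimSpec's RNG draws."""
    m, n = shape
    rng = np.random.default_rng(seed)
    b01, b10, b11 = beta
    v = np.empty((m, n))
    v[0, :] = rng.normal(boundary_mean, boundary_sd, size=n)
    v[1:, 0] = rng.normal(boundary_mean, boundary_sd, size=m - 1)
    e = rng.normal(0.0, innovation_sd, size=(m, n))
    for i in range(1, m):
        for j in range(1, n):
            v[i, j] = (
                b01 * v[i, j - 1] + b10 * v[i - 1, j] + b11 * v[i - 1, j - 1] + e[i, j]
            )
    return v
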