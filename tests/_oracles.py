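"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most literal method
available (dense linear algebra, explicit loops, closed forms) so they
share no code path with the package's implementations.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

_AXES = {"l": 1, "t": 0, "n": 2}


def dense_homogenized_sigma(mask: np.ndarray, direction: str,
                            sigma: float = 2.0) -> float:
    """Homogenized conductivity via a dense direct solve (brute force).

    Assembles the full linear system voxel by voxel with explicit loops
    and solves it with ``numpy.linalg.solve``; averages the plane current
    over the full cross-section.  Tractable only for tiny grids.
    """
    m = np.moveaxis(np.asarray(mask, dtype=bool), _AXES[direction], 0)
    n0, n1, n2 = m.shape
    comp, nc = ndi.label(m)  # default structure = face connectivity
    keep = [c for c in range(1, nc + 1)
            if (comp[0] == c).any() and (comp[-1] == c).any()]
    m = np.isin(comp, keep)
    if not m.any():
        return 0.0
    order = np.argwhere(m)
    idx = -np.ones(m.shape, dtype=int)
    for k, (i, j, l) in enumerate(order):
        idx[i, j, l] = k
    n = len(order)
    A = np.zeros((n, n))
    b = np.zeros(n)
    fixed = {}
    for k, (i, j, l) in enumerate(order):
        if i == 0:
            fixed[k] = 1.0
        elif i == n0 - 1:
            fixed[k] = -1.0
    for k, (i, j, l) in enumerate(order):
        if k in fixed:
            continue
        for di, dj, dl in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ii, jj, ll = i + di, j + dj, l + dl
            if 0 <= ii < n0 and 0 <= jj < n1 and 0 <= ll < n2 and m[ii, jj, ll]:
                A[k, k] += sigma
                A[k, idx[ii, jj, ll]] -= sigma
    for k, v in fixed.items():
        col = A[:, k].copy()
        b -= col * v
        A[:, k] = 0.0
        A[k, :] = 0.0
        A[k, k] = 1.0
        b[k] = v
    phi = np.linalg.solve(A, b)
    field = np.full(m.shape, np.nan)
    field[tuple(order.T)] = phi
    dphi = np.where(m[:-1] & m[1:], field[:-1] - field[1:], 0.0)
    j_planes = sigma * np.nansum(dphi.reshape(n0 - 1, -1), axis=1) / (n1 * n2)
    e_applied = 2.0 / (n0 - 1)
    return float(j_planes.mean() / e_applied)


def random_porous_mask(shape, rng, smooth: float = 1.2,
                       fill: float = 0.5) -> np.ndarray:
    """Smoothed random boolean mask with approximately ``fill`` density."""
    field = ndi.gaussian_filter(rng.random(shape), smooth)
    return field > np.quantile(field, 1.0 - fill)


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """(intercept, slopes) from the closed-form normal equations."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    A = np.hstack([np.ones((len(X), 1)), X])
    beta = np.linalg.inv(A.T @ A) @ A.T @ np.asarray(y, dtype=float)
    return float(beta[0]), beta[1:]
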