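"""Heller–Heller–Gorfine (HHG) distance-based independence test.

For every ordered pair of sample points (i, j) the remaining n-2 points are
cross-classified into a 2x2 table by whether they fall within radius
d_x(i, j) of i in x-space and within d_y(i, j) of i in y-space.  Pearson
chi-squared and likelihood-ratio (G) statistics of these tables are
aggregated over all pairs (sum statistics) and tracked for their maximum
(max statistics), giving four statistics in total; inference is by permuting
the y sample.  Tables with an empty margin contribute zero.

Scalar inputs use the absolute difference |x_i - x_j| as the distance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["hhg_statistics", "hhg_pvalues", "scalar_distance_matrix"]


def scalar_distance_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.abs(x[:, None] - x[None, :])


def _margins(d: np.ndarray) -> np.ndarray:
    """m[i, j] = #{k != i, j : d(i, k) <= d(i, j)} via per-row sorting."""
    n = d.shape[0]
    out = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        row = np.sort(d[i])
        # count of entries <= d[i, j], minus self (d[i,i]=0) and minus j itself
        out[i] = np.searchsorted(row, d[i], side="right") - 2
    np.fill_diagonal(out, 0)
    return out


@njit(cache=True)
def _hhg_kernel(dx, dyp, mx, myp):  # pragma: no cover - exercised via wrappers
    n = dx.shape[0]
    sum_chi = 0.0
    sum_lr = 0.0
    max_chi = 0.0
    max_lr = 0.0
    nf = float(n - 2)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rx = dx[i, j]
            ry = dyp[i, j]
            a11 = 0
            for k in range(n):
                if k == i or k == j:
                    continue
                if dx[i, k] <= rx and dyp[i, k] <= ry:
                    a11 += 1
            r1 = mx[i, j]
            c1 = myp[i, j]
            r2 = (n - 2) - r1
            c2 = (n - 2) - c1
            if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
                continue
            a12 = r1 - a11
            a21 = c1 - a11
            a22 = r2 - a21
            det = a11 * a22 - a12 * a21
            chi = nf * det * det / (float(r1) * r2 * c1 * c2)
            g = 0.0
            if a11 > 0:
                g += a11 * np.log(a11 * nf / (float(r1) * c1))
            if a12 > 0:
                g += a12 * np.log(a12 * nf / (float(r1) * c2))
            if a21 > 0:
                g += a21 * np.log(a21 * nf / (float(r2) * c1))
            if a22 > 0:
                g += a22 * np.log(a22 * nf / (float(r2) * c2))
            g *= 2.0
            sum_chi += chi
            sum_lr += g
            if chi > max_chi:
                max_chi = chi
            if g > max_lr:
                max_lr = g
    return sum_chi, sum_lr, max_chi, max_lr


def hhg_statistics(dx, dy) -> tuple[float, float, float, float]:
    """The four HHG statistics (sum.chisq, sum.lr, max.chisq, max.lr).

    ``dx`` and ``dy`` are square symmetric distance matrices over the same
    sample.
    """
    dx = np.ascontiguousarray(dx, dtype=float)
    dy = np.ascontiguousarray(dy, dtype=float)
    for d in (dx, dy):
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrices must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrices must be symmetric")
    if dx.shape != dy.shape:
        raise ValueError("distance matrices must share a shape")
    if dx.shape[0] < 5:
        raise ValueError("HHG needs n >= 5")
    mx = _margins(dx)
    my = _margins(dy)
    return tuple(float(v) for v in _hhg_kernel(dx, dy, mx, my))


def hhg_pvalues(
    x,
    y,
    n_perm: int = 999,
    seed: int = 0,
    return_observed: bool = False,
):
    """Permutation p-values of the four HHG statistics for two scalar samples.

    Distances are |x_i - x_j| and |y_i - y_j|; the y sample is permuted
    ``n_perm`` times and each p-value uses the add-one estimator
    ``(1 + #{S_perm >= S_obs}) / (1 + n_perm)``, so the attainable floor is
    ``1/(n_perm+1)``.  Reproducible given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    dx = scalar_distance_matrix(x)
    dy = scalar_distance_matrix(y)
    mx = _margins(dx)
    my = _margins(dy)
    observed = np.array(_hhg_kernel(dx, dy, mx, my))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(4, dtype=np.int64)
    tol = 1e-9 * np.maximum(1.0, np.abs(observed))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        idx = np.ix_(perm, perm)
        stat = np.array(_hhg_kernel(dx, dy[idx], mx, my[idx]))
        exceed += stat >= observed - tol
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    if return_observed:
        return tuple(map(float, pvals)), tuple(map(float, observed))
    return tuple(map(float, pvals))
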