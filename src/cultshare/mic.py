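"""Maximal Information Coefficient (MIC) from first principles.

MIC scans grids drawn over the scatter of (x, y): for every grid shape
(k columns, l rows) with k*l < n^alpha it finds (approximately) the grid of
that shape maximizing the mutual information of the induced discrete joint
distribution, normalizes by log2(min(k, l)), and reports the maximum over
shapes.  The column search for a fixed row partition is exact via dynamic
programming over "clumps" (maximal runs of x-ordered points that share a row,
with equal-x points kept atomic); the row partition is the tie-aware
equipartition of the y-axis, and both orientations of (x, y) are scanned.
The number of clumps fed to the DP is capped at c*k via a mass equipartition
("superclumps"), the standard approximation.

Defaults alpha=0.6, c=15 follow the original MINE statistic.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["mic", "mic_grid_values"]


def _plogp(a: np.ndarray) -> np.ndarray:
    """x*log2(x) with 0 log 0 = 0, elementwise on probabilities."""
    out = np.zeros_like(a, dtype=float)
    mask = a > 0
    out[mask] = a[mask] * np.log2(a[mask])
    return out


def _equipartition(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Tie-aware equipartition: bin index per point, <= n_bins bins.

    Points with equal values always share a bin; a tie group is appended to
    the current bin or opens a new one, whichever lands nearer the desired
    bin size (recomputed from what remains after each closed bin).
    """
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    sv = values[order]
    assign = np.empty(n, dtype=np.int64)
    desired = n / n_bins
    cur = 0
    in_cur = 0
    i = 0
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        size = j - i
        # close the current bin when appending the tie group would land
        # farther from the target size than the bin already is
        if in_cur != 0 and abs(in_cur + size - desired) > abs(in_cur - desired):
            cur += 1
            in_cur = 0
            rows_left = n_bins - cur
            if rows_left >= 1:
                desired = (n - i) / rows_left
        row = min(cur, n_bins - 1)
        assign[order[i:j]] = row
        in_cur += size
        i = j
    return assign


def _clump_counts(x: np.ndarray, q: np.ndarray, n_rows: int, max_clumps: int):
    """Collapse x-ordered points into clumps; return per-clump row counts.

    Equal-x tie groups are atomic: a pure group carries its row label and can
    merge with like-labelled neighbours, a mixed group is a clump by itself.
    If more than ``max_clumps`` clumps result, neighbouring clumps are merged
    by mass equipartition.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    qs = q[order]
    n = len(x)
    # tie groups of x -> (size, label or -1, row-count vector)
    groups = []
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        rows = qs[i:j]
        label = rows[0] if np.all(rows == rows[0]) else -1
        counts = np.bincount(rows, minlength=n_rows)
        groups.append((label, counts))
        i = j
    # merge consecutive pure groups with the same label
    clumps = []
    for label, counts in groups:
        if clumps and label >= 0 and clumps[-1][0] == label:
            clumps[-1][1] += counts
        else:
            clumps.append([label, counts.copy()])
    counts = np.array([c for _, c in clumps], dtype=float)  # (m, n_rows)
    m = len(counts)
    if m > max_clumps:
        sizes = counts.sum(axis=1)
        merged = np.zeros((max_clumps, n_rows))
        desired = n / max_clumps
        cur = 0
        in_cur = 0.0
        consumed = 0.0
        for t in range(m):
            size = sizes[t]
            if in_cur != 0 and abs(in_cur + size - desired) > abs(in_cur - desired):
                cur += 1
                in_cur = 0.0
                left = max_clumps - cur
                if left >= 1:
                    desired = (n - consumed) / left
            merged[min(cur, max_clumps - 1)] += counts[t]
            in_cur += size
            consumed += size
        counts = merged[merged.sum(axis=1) > 0]
    return counts


def _optimize_columns(counts: np.ndarray, k_max: int, n: int) -> np.ndarray:
    """Best mutual information for 2..k_max column bins over given clumps.

    ``counts`` is (m clumps x l rows).  Returns ``vals`` where ``vals[t]`` is
    the maximum I(P;Q) over partitions of the clumps into at most t bins.
    """
    m, l = counts.shape
    row_tot = counts.sum(axis=0)
    hq = -float(_plogp(row_tot / n).sum())
    # prefix sums over clumps
    C = np.vstack([np.zeros(l), np.cumsum(counts, axis=0)])  # (m+1, l)
    M = C.sum(axis=1)  # (m+1,)
    # bin objective for clumps (s, e]: -(nb/n)log(nb/n) + sum_r (nbr/n)log(nbr/n)
    NB = (M[None, :] - M[:, None]) / n              # (s, e)
    NBR = (C[None, :, :] - C[:, None, :]) / n       # (s, e, r)
    G = -_plogp(NB) + _plogp(NBR).sum(axis=2)
    k_cap = min(k_max, m)
    F = np.full((m + 1, k_cap + 1), -np.inf)
    F[1:, 1] = G[0, 1:]
    for t in range(2, k_cap + 1):
        # F[e, t] = max_s F[s, t-1] + G[s, e]
        cand = F[:, t - 1][:, None] + G
        F[:, t] = np.max(cand, axis=0)
    vals = np.full(k_max + 1, -np.inf)
    for t in range(2, k_max + 1):
        tt = min(t, k_cap)
        vals[t] = hq + np.nanmax(F[m, 1 : tt + 1])
    return np.maximum(vals, 0.0)


def mic_grid_values(x, y, alpha: float = 0.6, c: float = 15.0) -> dict:
    """Normalized characteristic-matrix entries {(k, l): value} actually scanned."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 10:
        raise ValueError("MIC needs n >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variation input")
    B = n**alpha
    entries: dict[tuple[int, int], float] = {}
    for ax, ay, transpose in ((x, y, False), (y, x, True)):
        max_l = int((B - 1e-12) / 2)
        for l in range(2, max_l + 1):
            k_max = int(math.ceil(B / l)) + 1
            while k_max * l >= B:
                k_max -= 1
            if k_max < 2:
                continue
            q = _equipartition(ay, l)
            n_rows = int(q.max()) + 1
            if n_rows < 2:
                continue  # ties collapsed the row partition entirely
            counts = _clump_counts(ax, q, n_rows, max(int(c * k_max), 1))
            vals = _optimize_columns(counts, k_max, n)
            for k in range(2, k_max + 1):
                key = (l, k) if transpose else (k, l)
                v = vals[k] / math.log2(min(k, l))
                if v > entries.get(key, 0.0):
                    entries[key] = v
    return entries


def mic(x, y, alpha: float = 0.6, c: float = 15.0) -> float:
    """Maximal Information Coefficient of two real vectors (symmetric in x, y)."""
    entries = mic_grid_values(x, y, alpha=alpha, c=c)
    return float(min(1.0, max(entries.values())))
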