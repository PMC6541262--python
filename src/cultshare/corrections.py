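"""Multiple-testing corrections: two FWER-conservative and five flexible ones.

Implements Bonferroni, Šidák, Holm, Hochberg, Hommel, Benjamini–Hochberg and
Benjamini–Yekutieli as adjusted p-values (the smallest family-wise alpha, or
FDR level, at which each hypothesis would be rejected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CORRECTION_METHODS", "CorrectedPValues", "adjust_pvalues"]

CORRECTION_METHODS = (
    "bonferroni",
    "sidak",
    "holm",
    "hochberg",
    "hommel",
    "bh",
    "by",
)


@dataclass(frozen=True)
class CorrectedPValues:
    method: str
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.raw)


def _holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj

def _hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")[::-1]  # largest first
    adj = np.empty(m)
    running = np.inf
    for rank, idx in enumerate(order):
        running = min(running, (rank + 1) * p[idx])
        adj[idx] = min(1.0, running)
    return adj

def _hommel(p: np.ndarray) -> np.ndarray:
    # Simes-based step procedure (Wright 1992 formulation of Hommel's method);
    # coincides with Hochberg below three hypotheses.
    m = len(p)
    if m < 3:
        return _hochberg(p)
    order = np.argsort(p, kind="stable")
    s = p[order]
    q = np.empty(m)
    pa = np.empty(m)
    q[:] = np.min(m * s / (np.arange(m) + 1.0))
    pa[:] = q
    for j in range(m - 1, 1, -1):
        lower = np.arange(0, m - j + 1)      # smallest m-j+1 order statistics
        upper = np.arange(m - j + 1, m)      # largest j-1 of them
        q1 = np.min(j * s[upper] / (np.arange(2, j + 1)))
        q[lower] = np.minimum(j * s[lower], q1)
        q[upper] = q[m - j]
        pa = np.maximum(pa, q)
    adj = np.empty(m)
    adj[order] = np.minimum(1.0, np.maximum(pa, s))
    return adj

def _bh(p: np.ndarray, factor: float = 1.0) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")[::-1]
    adj = np.empty(m)
    running = np.inf
    for rank, idx in enumerate(order):
        k = m - rank  # rank from smallest, 1-based
        running = min(running, factor * m / k * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def adjust_pvalues(raw, method: str) -> CorrectedPValues:
    """Adjusted p-values for one correction family.

    ``method`` is one of :data:`CORRECTION_METHODS`.  Raw p-values must lie in
    (0, 1].  Benjamini–Yekutieli uses the harmonic factor c(m) = sum_{i<=m} 1/i.
    """
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("raw p-values must be a non-empty 1-d sequence")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("raw p-values must lie in (0, 1]")
    m = len(p)
    if method == "bonferroni":
        adj = np.minimum(1.0, m * p)
    elif method == "sidak":
        adj = 1.0 - (1.0 - p) ** m
    elif method == "holm":
        adj = _holm(p)
    elif method == "hochberg":
        adj = _hochberg(p)
    elif method == "hommel":
        adj = _hommel(p) if m > 1 else p.copy()
    elif method == "bh":
        adj = _bh(p)
    elif method == "by":
        adj = _bh(p, factor=float(np.sum(1.0 / (np.arange(m) + 1.0))))
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return CorrectedPValues(method=method, raw=tuple(p), adjusted=tuple(adj))
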