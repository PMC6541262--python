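"""Stage-5 dependence screen: MIC, distance correlation and HHG.

Screens the pairwise Hamming-distance vector against geographic distance and
each transformed covariate column (plus itself, as a positive-control row),
reporting MIC and dCor as association strengths and the four HHG permutation
p-values as evidence of dependence, with Bonferroni/Holm/Hochberg corrections
applied per p-value family across the 23 rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cultshare.corrections import adjust_pvalues
from cultshare.hhg import hhg_pvalues, hhg_statistics, scalar_distance_matrix
from cultshare.mic import mic

__all__ = [
    "DependenceResult",
    "mic",
    "distance_correlation",
    "hhg_statistics",
    "hhg_pvalues",
    "dependence_screen",
]

SCREEN_CORRECTIONS = ("bonferroni", "holm", "hochberg")
HHG_FAMILIES = ("pval_sc", "pval_sl", "pval_mc", "pval_ml")


@dataclass(frozen=True)
class DependenceResult:
    """One screen row: association strengths and HHG permutation p-values."""

    variable: str
    mic: float
    dcor: float
    pval_sc: float
    pval_sl: float
    pval_mc: float
    pval_ml: float


def distance_correlation(x, y) -> float:
    """Sample distance correlation of two real vectors (V-statistic form).

    Double-centres the absolute-difference distance matrices; returns
    dCov / sqrt(dVar_x * dVar_y), clipped to [0, 1].  Constant input is a
    degenerate case (dVar = 0) and yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 4:
        raise ValueError("distance correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    a = scalar_distance_matrix(x)
    b = scalar_distance_matrix(y)
    A = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
    B = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.clip(np.sqrt(max(0.0, dcov2) / np.sqrt(dvarx * dvary)), 0.0, 1.0))


def dependence_screen(
    pairs: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Screen the Hamming column of a pairwise table against every regressor.

    One row per column of {geo_km, delta_* covariates, hamming itself}; the
    self-comparison row is retained as a positive control and enters the
    correction families like any other row.  Returns the screen table and one
    corrected table per HHG p-value family (Bonferroni, Holm, Hochberg).
    """
    if "hamming" not in pairs.columns:
        raise ValueError("pairwise table must have a 'hamming' column")
    target = pairs["hamming"].to_numpy(dtype=float)
    columns = ["geo_km"] + [c for c in pairs.columns if c.startswith("delta_")]
    columns.append("hamming")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(columns))]
    rows = []
    for col, col_seed in zip(columns, seeds):
        yv = pairs[col].to_numpy(dtype=float)
        pvals = hhg_pvalues(target, yv, n_perm=n_perm, seed=col_seed)
        rows.append(
            DependenceResult(
                variable=col,
                mic=mic(target, yv),
                dcor=distance_correlation(target, yv),
                pval_sc=pvals[0],
                pval_sl=pvals[1],
                pval_mc=pvals[2],
                pval_ml=pvals[3],
            )
        )
    screen = pd.DataFrame([r.__dict__ for r in rows])
    corrected: dict[str, pd.DataFrame] = {}
    for family in HHG_FAMILIES:
        raw = screen[family].to_numpy()
        table = screen[["variable", family]].copy()
        for method in SCREEN_CORRECTIONS:
            table[f"adj_{method}"] = adjust_pvalues(raw, method).adjusted
        corrected[family] = table
    return screen, corrected
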