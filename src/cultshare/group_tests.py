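"""Stage-1 exploratory battery: practice presence vs covariate location shift.

For each (practice, variable) combination the societies are split into the
group exhibiting the practice and the group lacking it, and the two samples
are compared with a two-sample test chosen by an assumption-based router:

* normality (Shapiro–Wilk per group) and variance homogeneity
  (Brown–Forsythe) both pass → Student t-test;
* normality fails but homogeneity passes → Wilcoxon–Mann–Whitney;
* homogeneity fails → the three tests robust to it are all reported:
  Fligner–Policello, Brunner–Munzel and Wilcoxon–Mann–Whitney.

With 14 practices and 21 covariates the sweep schedules 294 combinations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cultshare.corrections import CORRECTION_METHODS, adjust_pvalues
from cultshare.data import PRACTICE_CODES, SocietyDataset

__all__ = [
    "TestResult",
    "split_by_practice",
    "t_test",
    "wilcoxon_mann_whitney",
    "fligner_policello",
    "brunner_munzel",
    "route_and_test",
    "exploratory_sweep",
    "sweep_corrections",
]

MIN_GROUP_SIZE = 3
MIN_GROUP_SIZE_BM = 4  # Brunner-Munzel variance estimate needs >= 4 per group


@dataclass(frozen=True)
class TestResult:
    """One two-sample test outcome, with routing metadata."""

    test_name: str
    statistic: float
    p_value: float
    n_present: int
    n_absent: int
    practice: str | None = None
    variable: str | None = None
    assumption_flags: dict = field(default_factory=dict)
    degenerate: bool = False
    note: str = ""


def split_by_practice(dataset: SocietyDataset, practice: str, variable: str):
    """Covariate values of societies with vs without a practice.

    Returns ``(values_present, values_absent)`` as float arrays covering all
    societies.  Raises if the covariate is missing anywhere.
    """
    if practice not in PRACTICE_CODES:
        raise ValueError(f"unknown practice code {practice!r}")
    present, absent = [], []
    for s in dataset.societies:
        v = s.covariates.get(variable)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"society {s.name!r}: missing covariate {variable!r}")
        (present if practice in s.practices else absent).append(float(v))
    return np.asarray(present), np.asarray(absent)


def _degenerate(g1, g2) -> TestResult | None:
    """Zero-variance guard shared by all tests."""
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        same = g1[0] == g2[0]
        return TestResult(
            test_name="degenerate",
            statistic=0.0,
            p_value=1.0 if same else np.nan,
            n_present=len(g1),
            n_absent=len(g2),
            degenerate=True,
            note="zero variance in both groups",
        )
    return None


def t_test(g1, g2) -> TestResult:
    """Student (pooled-variance) two-sample t-test, two-sided."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    deg = _degenerate(g1, g2)
    if deg is not None:
        return TestResult(**{**deg.__dict__, "test_name": "t"})
    stat, p = stats.ttest_ind(g1, g2, equal_var=True)
    return TestResult("t", float(stat), float(p), len(g1), len(g2))


def _wmw_exact_p(g1, g2) -> float:
    """Exact two-sided WMW p by full enumeration of group labelings."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    ranks = stats.rankdata(pooled)
    mu = n1 * len(g2) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    d_obs = abs(ranks[:n1].sum() - offset - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_mann_whitney(g1, g2, exact_if_small: bool = True) -> TestResult:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Exact null enumeration when n1+n2 <= 12 and there are no ties; otherwise
    the normal approximation with mid-ranks, tie-corrected variance and
    continuity correction.  The reported statistic is the standardized U.
    """
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    deg = _degenerate(g1, g2)
    if deg is not None:
        return TestResult(**{**deg.__dict__, "test_name": "wmw"})
    n1, n2 = len(g1), len(g2)
    pooled = np.concatenate([g1, g2])
    no_ties = len(np.unique(pooled)) == len(pooled)
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult("wmw", 0.0, 1.0, n1, n2, degenerate=True,
                          note="zero rank variance")
    cc = 0.5 if abs(u1 - mu) > 0 else 0.0
    z = (u1 - mu - np.sign(u1 - mu) * cc) / np.sqrt(var)
    if exact_if_small and no_ties and n <= 12:
        p = _wmw_exact_p(g1, g2)
        method = "exact"
    else:
        p = 2.0 * stats.norm.sf(abs(z))
        method = "asymptotic"
    return TestResult("wmw", float(z), float(min(1.0, p)), n1, n2,
                      note=method)


def fligner_policello(g1, g2) -> TestResult:
    """Fligner–Policello robust rank-order test, two-sided.

    Placement-based: P_i = #{y < x_i}, Q_j = #{x < y_j} (ties count 1/2);
    statistic (sum P - sum Q) / (2 sqrt(V_P + V_Q + Pbar*Qbar)) referred to a
    standard normal.
    """
    x, y = np.asarray(g1, float), np.asarray(g2, float)
    deg = _degenerate(x, y)
    if deg is not None:
        return TestResult(**{**deg.__dict__, "test_name": "fligner_policello"})
    P = np.array([(y < xi).sum() + 0.5 * (y == xi).sum() for xi in x])
    Q = np.array([(x < yj).sum() + 0.5 * (x == yj).sum() for yj in y])
    Pbar, Qbar = P.mean(), Q.mean()
    V1 = np.sum((P - Pbar) ** 2)
    V2 = np.sum((Q - Qbar) ** 2)
    denom = 2.0 * np.sqrt(V1 + V2 + Pbar * Qbar)
    if denom == 0:
        num = P.sum() - Q.sum()
        if num == 0:
            return TestResult("fligner_policello", 0.0, 1.0, len(x), len(y),
                              degenerate=True, note="zero placement variance")
        # complete separation: every x-placement 0 and every y-placement full
        return TestResult(
            "fligner_policello", float(np.sign(num) * np.inf),
            float(np.finfo(float).tiny), len(x), len(y),
            degenerate=True, note="complete separation",
        )
    u_hat = (P.sum() - Q.sum()) / denom
    p = 2.0 * stats.norm.sf(abs(u_hat))
    return TestResult("fligner_policello", float(u_hat), float(p), len(x), len(y))


def brunner_munzel(g1, g2) -> TestResult:
    """Brunner–Munzel test (t reference, Welch–Satterthwaite df), two-sided."""
    x, y = np.asarray(g1, float), np.asarray(g2, float)
    deg = _degenerate(x, y)
    if deg is not None:
        return TestResult(**{**deg.__dict__, "test_name": "brunner_munzel"})
    if np.array_equal(np.sort(x), np.sort(y)):
        return TestResult("brunner_munzel", 0.0, 1.0, len(x), len(y),
                          note="identical samples")
    stat, p = stats.brunnermunzel(x, y, distribution="t")
    if not np.isfinite(stat):
        return TestResult("brunner_munzel", np.nan, np.nan, len(x), len(y),
                          degenerate=True, note="separated samples")
    return TestResult("brunner_munzel", float(stat), float(p), len(x), len(y))


def relative_effect(g1, g2) -> float:
    """Nonparametric relative effect p_hat = P(X < Y) + 0.5 P(X = Y)."""
    x, y = np.asarray(g1, float), np.asarray(g2, float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    ry = ranks[len(x):].mean()
    return float((ry - (len(y) + 1) / 2.0) / len(x))


def route_and_test(g1, g2, alpha_assumptions: float = 0.05) -> list[TestResult]:
    """Assumption-checked routing to the appropriate test(s).

    Shapiro–Wilk per group and Brown–Forsythe (median-centred Levene) decide:
    both pass → t only; only normality fails → WMW only; homogeneity fails →
    Fligner–Policello + Brunner–Munzel + WMW.  Groups smaller than 3 raise;
    Brunner–Munzel is skipped (with a note) below 4 per group.
    """
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if len(g1) < MIN_GROUP_SIZE or len(g2) < MIN_GROUP_SIZE:
        raise ValueError("insufficient group size (need >= 3 per group)")
    flags = {}
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        # Shapiro is undefined on constant input; a constant group can never
        # pass the normality screen.
        flags["normal_present"] = np.ptp(g1) != 0 and stats.shapiro(g1).pvalue > alpha_assumptions
        flags["normal_absent"] = np.ptp(g2) != 0 and stats.shapiro(g2).pvalue > alpha_assumptions
        flags["equal_variance"] = False
    else:
        flags["normal_present"] = bool(stats.shapiro(g1).pvalue > alpha_assumptions)
        flags["normal_absent"] = bool(stats.shapiro(g2).pvalue > alpha_assumptions)
        flags["equal_variance"] = bool(
            stats.levene(g1, g2, center="median").pvalue > alpha_assumptions
        )
    normal = flags["normal_present"] and flags["normal_absent"]
    if normal and flags["equal_variance"]:
        results = [t_test(g1, g2)]
        route = "t"
    elif flags["equal_variance"]:
        results = [wilcoxon_mann_whitney(g1, g2)]
        route = "wmw"
    else:
        results = [fligner_policello(g1, g2)]
        if min(len(g1), len(g2)) >= MIN_GROUP_SIZE_BM:
            results.append(brunner_munzel(g1, g2))
        results.append(wilcoxon_mann_whitney(g1, g2))
        route = "fp+bm+wmw"
    flags["route"] = route
    return [
        TestResult(**{**r.__dict__, "assumption_flags": dict(flags)})
        for r in results
    ]


def exploratory_sweep(
    dataset: SocietyDataset, alpha_assumptions: float = 0.05
) -> pd.DataFrame:
    """Run the routed battery over every (practice, variable) combination.

    Returns one row per reported test.  The frame's ``attrs`` carry
    ``n_scheduled`` (practice x variable combinations) and ``n_skipped``
    (combinations whose smaller group has < 3 societies).
    """
    dataset.require_covariates()
    rows = []
    n_scheduled = 0
    n_skipped = 0
    for practice in PRACTICE_CODES:
        for variable in dataset.variable_roster:
            n_scheduled += 1
            g1, g2 = split_by_practice(dataset, practice, variable)
            if len(g1) < MIN_GROUP_SIZE or len(g2) < MIN_GROUP_SIZE:
                n_skipped += 1
                rows.append(
                    {
                        "practice": practice,
                        "variable": variable,
                        "test_name": "skipped",
                        "statistic": np.nan,
                        "p_value": np.nan,
                        "n_present": len(g1),
                        "n_absent": len(g2),
                        "route": "insufficient group size",
                        "note": "insufficient group size",
                    }
                )
                continue
            for r in route_and_test(g1, g2, alpha_assumptions):
                rows.append(
                    {
                        "practice": practice,
                        "variable": variable,
                        "test_name": r.test_name,
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "n_present": r.n_present,
                        "n_absent": r.n_absent,
                        "route": r.assumption_flags.get("route", ""),
                        "note": r.note,
                    }
                )
    frame = pd.DataFrame(rows)
    frame.attrs["n_scheduled"] = n_scheduled
    frame.attrs["n_skipped"] = n_skipped
    return frame


def sweep_corrections(results: pd.DataFrame) -> pd.DataFrame:
    """Adjusted p-values for every reported test row, one column per method.

    The correction family is the full set of reported (finite) p-values from
    the sweep, so conservative methods scale with everything that was run.
    """
    mask = results["p_value"].notna()
    raw = results.loc[mask, "p_value"].to_numpy()
    out = results.loc[mask, ["practice", "variable", "test_name", "p_value"]].copy()
    for method in CORRECTION_METHODS:
        out[f"adj_{method}"] = adjust_pvalues(raw, method).adjusted
    return out.reset_index(drop=True)
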