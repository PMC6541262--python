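"""Stage-6 predictive-null comparison via nested cross-validation + ANOVA.

Four regression learners (random forest, gradient boosting, rotation forest,
RBF support-vector regression) and a mean-prediction baseline are evaluated
on identical outer folds of a ten-fold nested cross-validation: inner k-fold
grid search selects hyperparameters on each outer-train split, the refitted
model is scored (MSE) on the outer-test split.  A one-way fixed-effects ANOVA
with method as the factor then asks whether any learner beats predicting the
mean — the operational definition of "a multivariate pattern exists".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from cultshare.rotation_forest import RotationForestRegressor

__all__ = [
    "AnovaResult",
    "default_methods",
    "mean_baseline_fit_predict",
    "nested_cv",
    "anova_on_folds",
    "pattern_test",
]

METHOD_ORDER = ("random_forest", "boosting", "rotation_forest", "svm_rbf", "mean_baseline")


def mean_baseline_fit_predict(train_y, test_n: int) -> np.ndarray:
    """Predict the training mean everywhere (the null reference model)."""
    train_y = np.asarray(train_y, dtype=float)
    if len(train_y) == 0:
        raise ValueError("training response must be non-empty")
    return np.full(int(test_n), train_y.mean())


def default_methods(n_features: int, light: bool = False) -> dict:
    """Estimator + hyperparameter grid per method.

    ``light=True`` shrinks ensembles and grids for simulation studies where
    the comparison of interest is learner-vs-baseline, not learner-vs-learner.
    """
    p = n_features
    if light:
        return {
            "random_forest": (
                RandomForestRegressor(n_estimators=100),
                {"max_features": ["sqrt"]},
            ),
            "boosting": (
                GradientBoostingRegressor(n_estimators=100, learning_rate=0.1),
                {"max_depth": [2]},
            ),
            "rotation_forest": (
                RotationForestRegressor(n_estimators=10, sample_fraction=0.75),
                {"n_feature_subsets": [3]},
            ),
            "svm_rbf": (
                Pipeline([("scale", StandardScaler()), ("svr", SVR(epsilon=0.1))]),
                {"svr__C": [1.0, 100.0], "svr__gamma": [1.0 / p]},
            ),
            "mean_baseline": (DummyRegressor(strategy="mean"), {}),
        }
    return {
        "random_forest": (
            RandomForestRegressor(n_estimators=500),
            {"max_features": [max(1, p // 3), "sqrt", 1.0]},
        ),
        "boosting": (
            GradientBoostingRegressor(n_estimators=500),
            {"max_depth": [1, 2, 3], "learning_rate": [0.05, 0.1]},
        ),
        "rotation_forest": (
            RotationForestRegressor(n_estimators=10, sample_fraction=0.75),
            {"n_feature_subsets": [2, 3]},
        ),
        "svm_rbf": (
            Pipeline([("scale", StandardScaler()), ("svr", SVR(epsilon=0.1))]),
            {
                "svr__C": [0.1, 1.0, 10.0, 100.0],
                "svr__gamma": [0.1 / p, 1.0 / p, 10.0 / p],
            },
        ),
        "mean_baseline": (DummyRegressor(strategy="mean"), {}),
    }


def _seed_estimator(est, seed: int):
    params = est.get_params()
    if "random_state" in params:
        est.set_params(random_state=seed)
    else:
        for key in params:
            if key.endswith("__random_state"):
                est.set_params(**{key: seed})
    return est


def nested_cv(
    X,
    y,
    methods: dict | None = None,
    k_outer: int = 10,
    k_inner: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Outer-fold x method MSE table from nested cross-validation.

    Every method sees identical outer splits (paired design); the inner grid
    search minimizes MSE.  Deterministic given ``seed``.  The returned frame
    carries the outer test indices in ``attrs['fold_indices']``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) < 2 * k_outer:
        raise ValueError("need at least 2 rows per outer fold")
    if methods is None:
        methods = default_methods(X.shape[1])
    for name, (_, grid) in methods.items():
        if grid is None:
            raise ValueError(f"method {name!r}: grid must be a dict (may be empty)")
    ss = np.random.SeedSequence(seed)
    outer_seed = int(ss.generate_state(1)[0] % (2**31))
    outer = KFold(n_splits=k_outer, shuffle=True, random_state=outer_seed)
    fold_seeds = ss.spawn(k_outer)
    Xv = X.to_numpy(dtype=float)
    records = np.zeros((k_outer, len(methods)))
    fold_indices = []
    names = list(methods)
    for f, (tr, te) in enumerate(outer.split(Xv)):
        fold_indices.append([int(i) for i in te])
        per_method = np.random.SeedSequence(
            int(fold_seeds[f].generate_state(1)[0] % (2**31))
        ).spawn(len(methods))
        for m, name in enumerate(names):
            est, grid = methods[name]
            est = _seed_estimator(
                clone(est), int(per_method[m].generate_state(1)[0] % (2**31))
            )
            n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 0
            if n_combos == 1:  # inner search is a no-op: set params directly
                est.set_params(**{k: v[0] for k, v in grid.items()})
                grid = {}
            if grid:
                inner_seed = int(per_method[m].generate_state(2)[1] % (2**31))
                search = GridSearchCV(
                    est,
                    grid,
                    scoring="neg_mean_squared_error",
                    cv=KFold(n_splits=k_inner, shuffle=True, random_state=inner_seed),
                    refit=True,
                )
                search.fit(Xv[tr], y[tr])
                pred = search.predict(Xv[te])
            else:
                est.fit(Xv[tr], y[tr])
                pred = est.predict(Xv[te])
            records[f, m] = float(np.mean((pred - y[te]) ** 2))
    table = pd.DataFrame(
        records, columns=names, index=[f"fold_{f+1}" for f in range(k_outer)]
    )
    table.attrs["fold_indices"] = fold_indices
    return table


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA summary (method as the factor)."""

    df_model: int
    df_residual: int
    ss_model: float
    ss_residual: float
    ms_model: float
    ms_residual: float
    F: float
    p: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Df": [self.df_model, self.df_residual],
                "Sum Sq": [self.ss_model, self.ss_residual],
                "Mean Sq": [self.ms_model, self.ms_residual],
                "F value": [self.F, np.nan],
                "Pr(>F)": [self.p, np.nan],
            },
            index=["Model", "Residuals"],
        )


def anova_on_folds(table: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA on fold MSEs with method as the grouping factor.

    Fold MSEs are treated as independent observations, matching the
    conventional df structure (methods-1, methods*(folds-1)); the fold
    pairing is deliberately ignored (see the methods note for the caveat).
    """
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("fold MSE table contains non-finite values")
    k_folds, n_methods = values.shape
    grand = values.mean()
    ss_model = k_folds * float(((values.mean(axis=0) - grand) ** 2).sum())
    ss_residual = float(((values - values.mean(axis=0, keepdims=True)) ** 2).sum())
    df_model = n_methods - 1
    df_residual = n_methods * (k_folds - 1)
    ms_model = ss_model / df_model
    if ss_residual <= 0:
        if ss_model <= 0:  # all cells equal: zero total variance
            return AnovaResult(
                df_model, df_residual, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, degenerate=True
            )
        return AnovaResult(
            df_model, df_residual, ss_model, 0.0, ms_model, 0.0,
            np.inf, 0.0, degenerate=True,
        )
    ms_residual = ss_residual / df_residual
    F = ms_model / ms_residual
    p = float(stats.f.sf(F, df_model, df_residual))
    return AnovaResult(
        df_model, df_residual, ss_model, ss_residual, ms_model, ms_residual,
        float(F), p,
    )


def pattern_test(
    pairs: pd.DataFrame,
    methods: dict | None = None,
    k_outer: int = 10,
    k_inner: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    light: bool = False,
) -> dict:
    """Any-multivariate-pattern test on a pairwise design table.

    Response = Hamming distance; regressors = geographic distance + the 21
    covariate-difference columns.  Returns the fold MSE table, the ANOVA, and
    a verdict: "no detectable pattern" when the ANOVA p >= ``alpha``.
    """
    regressors = ["geo_km"] + [c for c in pairs.columns if c.startswith("delta_")]
    X = pairs[regressors]
    y = pairs["hamming"].to_numpy(dtype=float)
    if methods is None:
        methods = default_methods(X.shape[1], light=light)
    table = nested_cv(X, y, methods=methods, k_outer=k_outer, k_inner=k_inner, seed=seed)
    anova = anova_on_folds(table)
    verdict = "no detectable pattern" if anova.p >= alpha else "pattern detected"
    return {
        "fold_mse": table,
        "anova": anova,
        "verdict": verdict,
        "n_regressors": X.shape[1],
    }
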