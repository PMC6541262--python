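"""Synthetic society datasets with controlled statistical structure.

The generator emulates the shape of the real data — ~22 societies, 14 binary
practices with marginal frequencies matching the reference inventory, 21
continuous/count covariates, geographic coordinates — under three regimes
that realize the competing hypotheses the analysis pipeline is built to
discriminate:

``null``
    practices independent of all covariates and of geography (no effect);
``covariate_effect``
    practice k present with probability ``logistic(logit(p_k) + beta * z)``
    where ``z`` is the standardized value of a chosen driving covariate
    (local-adaptation hypothesis);
``diffusion``
    the same logistic bump driven by a Gaussian spatial random field with a
    tunable correlation length, so nearby societies share practices
    (cultural-diffusion hypothesis).

Covariates are independent Gaussians except population size (log-normal) and
the five subsistence percentages (Dirichlet, renormalized to sum 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cultshare.data import (
    PRACTICE_CODES,
    SUBSISTENCE_VARIABLES,
    VARIABLE_ROSTER,
    SocietyDataset,
    SocietyRecord,
    builtin_fixture,
    encode_practices,
)
from cultshare.dissimilarity import great_circle_km

__all__ = [
    "SyntheticConfig",
    "practice_marginals_from_fixture",
    "generate_dataset",
    "attach_synthetic_covariates",
    "generate_regression_problem",
    "noise_sd_for_r2",
    "LINEAR_SIGNAL_COLUMNS",
    "LINEAR_SIGNAL_COEFS",
]

REGIMES = ("null", "covariate_effect", "diffusion")

# Plausible cross-cultural location/scale for each Gaussian covariate.
_COVARIATE_MEANS: dict[str, float] = {
    "annual_mean_temperature": 8.0,
    "annual_temperature_variance": 60.0,
    "temperature_constancy": 0.45,
    "temperature_contingency": 0.30,
    "annual_mean_precipitation": 900.0,
    "annual_precipitation_variance": 5000.0,
    "precipitation_constancy": 0.40,
    "precipitation_contingency": 0.30,
    "distance_to_coast": 300.0,
    "elevation": 600.0,
    "slope": 3.0,
    "monthly_mean_npp": 45.0,
    "annual_npp_variance": 300.0,
    "npp_constancy": 0.50,
    "npp_contingency": 0.25,
}
_COVARIATE_SDS: dict[str, float] = {
    "annual_mean_temperature": 12.0,
    "annual_temperature_variance": 25.0,
    "temperature_constancy": 0.15,
    "temperature_contingency": 0.10,
    "annual_mean_precipitation": 450.0,
    "annual_precipitation_variance": 2200.0,
    "precipitation_constancy": 0.13,
    "precipitation_contingency": 0.10,
    "distance_to_coast": 250.0,
    "elevation": 450.0,
    "slope": 2.0,
    "monthly_mean_npp": 22.0,
    "annual_npp_variance": 180.0,
    "npp_constancy": 0.15,
    "npp_contingency": 0.10,
}
# Population size: log-normal parameters (on the natural-log scale).
_LOG_POP_MEAN = 6.2
_LOG_POP_SD = 1.0
# Subsistence mix: Dirichlet concentrations for
# (hunting, gathering, animal_husbandry, fishing, agriculture).
_SUBSISTENCE_ALPHA = (2.5, 1.5, 0.8, 2.0, 1.2)


def practice_marginals_from_fixture() -> pd.Series:
    """Empirical presence frequency of each practice in the 22-society inventory."""
    m = encode_practices(builtin_fixture())
    return m.mean(axis=0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for :func:`generate_dataset`.

    ``beta`` is the effect size in log-odds per standard deviation of the
    driving covariate (``covariate_effect``) or per unit of the spatial field
    (``diffusion``); it is forced to 0 under the ``null`` regime.
    """

    n_societies: int = 22
    regime: str = "null"
    beta: float = 0.0
    driving_variable: str = "annual_mean_temperature"
    affected_practices: tuple[str, ...] | None = None
    practice_base_freqs: tuple[float, ...] | None = None
    covariate_means: dict[str, float] = field(default_factory=lambda: dict(_COVARIATE_MEANS))
    covariate_sds: dict[str, float] = field(default_factory=lambda: dict(_COVARIATE_SDS))
    coordinate_box: tuple[tuple[float, float], tuple[float, float]] = (
        (-55.0, 71.0),
        (-180.0, 180.0),
    )
    diffusion_range_km: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.n_societies < 3:
            raise ValueError("n_societies must be >= 3 (pairwise stages need >= 3)")
        if self.practice_base_freqs is not None:
            freqs = tuple(self.practice_base_freqs)
            if len(freqs) != len(PRACTICE_CODES):
                raise ValueError("practice_base_freqs must have 14 entries")
            if not all(0.0 <= p <= 1.0 for p in freqs):
                raise ValueError("practice_base_freqs must lie in [0, 1]")
        if any(sd <= 0 for sd in self.covariate_sds.values()):
            raise ValueError("covariate sds must be positive")
        if self.affected_practices is not None:
            bad = set(self.affected_practices) - set(PRACTICE_CODES)
            if bad:
                raise ValueError(f"unknown affected practice(s): {sorted(bad)}")
        if self.regime == "null" and self.beta != 0.0:
            object.__setattr__(self, "beta", 0.0)

    @property
    def base_freqs(self) -> np.ndarray:
        if self.practice_base_freqs is not None:
            return np.asarray(self.practice_base_freqs, dtype=float)
        return practice_marginals_from_fixture().to_numpy()


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(p / (1.0 - p))


def _spatial_field(
    lats: np.ndarray, lons: np.ndarray, range_km: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of a unit-variance Gaussian field with exponential covariance."""
    n = len(lats)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = great_circle_km((lats[i], lons[i]), (lats[j], lons[j]))
    cov = np.exp(-d / range_km)
    cov[np.diag_indices(n)] += 1e-8  # numerical jitter for the Cholesky factor
    return np.linalg.cholesky(cov) @ rng.standard_normal(n)


def generate_dataset(config: SyntheticConfig) -> SocietyDataset:
    """Draw one synthetic :class:`~cultshare.data.SocietyDataset`.

    Fully reproducible given ``config.seed``.  A society whose practice draw
    comes up empty is redrawn (datasets require non-empty practice sets); the
    redraw uses only the practice stream, so covariate independence under the
    null regime is preserved.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    r_coord, r_cov, r_prac, r_field = (np.random.default_rng(s) for s in ss.spawn(4))

    n = cfg.n_societies
    (lat_lo, lat_hi), (lon_lo, lon_hi) = cfg.coordinate_box
    lats = r_coord.uniform(lat_lo, lat_hi, n)
    lons = r_coord.uniform(lon_lo, lon_hi, n)

    cov = {}
    for v in VARIABLE_ROSTER:
        if v == "population_size" or v in SUBSISTENCE_VARIABLES:
            continue
        cov[v] = r_cov.normal(cfg.covariate_means[v], cfg.covariate_sds[v], n)
    cov["population_size"] = np.exp(r_cov.normal(_LOG_POP_MEAN, _LOG_POP_SD, n))
    shares = r_cov.dirichlet(_SUBSISTENCE_ALPHA, size=n) * 100.0
    for k, v in enumerate(SUBSISTENCE_VARIABLES):
        cov[v] = shares[:, k]

    base = _logit(cfg.base_freqs)  # (14,)
    affected = np.ones(len(PRACTICE_CODES), dtype=bool)
    if cfg.affected_practices is not None:
        affected = np.isin(np.array(PRACTICE_CODES), cfg.affected_practices)
    if cfg.regime == "covariate_effect" and cfg.beta != 0.0:
        x = cov[cfg.driving_variable]
        z = (x - np.mean(x)) / np.std(x)
        shift = cfg.beta * z[:, None] * affected[None, :]
    elif cfg.regime == "diffusion" and cfg.beta != 0.0:
        fields = np.column_stack(
            [
                _spatial_field(lats, lons, cfg.diffusion_range_km, r_field)
                for _ in PRACTICE_CODES
            ]
        )
        shift = cfg.beta * fields * affected[None, :]
    else:
        shift = np.zeros((n, len(PRACTICE_CODES)))
    prob = 1.0 / (1.0 + np.exp(-(base[None, :] + shift)))

    societies = []
    for i in range(n):
        present = r_prac.random(len(PRACTICE_CODES)) < prob[i]
        tries = 0
        while not present.any():  # practice sets must be non-empty
            present = r_prac.random(len(PRACTICE_CODES)) < prob[i]
            tries += 1
            if tries >= 100:  # all probabilities ~0: force the likeliest code
                present[int(np.argmax(prob[i]))] = True
        societies.append(
            SocietyRecord(
                name=f"synthetic-{i:03d}",
                latitude=float(lats[i]),
                longitude=float(lons[i]),
                practices=frozenset(
                    c for c, p in zip(PRACTICE_CODES, present) if p
                ),
                covariates={v: float(cov[v][i]) for v in VARIABLE_ROSTER},
            )
        )
    return SocietyDataset(tuple(societies))


def attach_synthetic_covariates(
    dataset: SocietyDataset, seed: int = 0
) -> SocietyDataset:
    """Join null-regime synthetic coordinates and covariates onto a dataset.

    Useful for exercising covariate-dependent stages with the embedded
    practice inventory, whose coordinates and covariates are not bundled.
    Practice sets are untouched.
    """
    donor = generate_dataset(
        SyntheticConfig(n_societies=len(dataset), regime="null", seed=seed)
    )
    frame = donor.covariate_frame()
    frame.index = dataset.names
    frame["latitude"] = [s.latitude for s in donor.societies]
    frame["longitude"] = [s.longitude for s in donor.societies]
    return dataset.with_joined(frame)


# ---------------------------------------------------------------------------
# Regression test-bed mimicking the transformed pairwise design

#: Columns carrying the signal in the linear/nonlinear regimes.
LINEAR_SIGNAL_COLUMNS = (
    "delta_annual_mean_temperature",
    "delta_elevation",
    "delta_hunting",
)
#: True coefficients of the linear signal (columns are unit-variance).
LINEAR_SIGNAL_COEFS = (2.0, -1.5, 1.0)


def noise_sd_for_r2(target_r2: float) -> float:
    """Noise standard deviation giving a target population R^2 for the linear signal."""
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    signal_var = float(np.sum(np.square(LINEAR_SIGNAL_COEFS)))
    return float(np.sqrt(signal_var * (1.0 - target_r2) / target_r2))


def generate_regression_problem(
    n_pairs: int,
    signal: str = "none",
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """A 22-column regressor table shaped like the pairwise design, plus response.

    ``signal='none'`` yields pure noise (population R^2 of any predictor is 0);
    ``'linear'`` adds ``2*z1 - 1.5*z2 + z3`` over :data:`LINEAR_SIGNAL_COLUMNS`;
    ``'nonlinear'`` adds ``sin(2*z1) + z2**2 - 1 + z3*z2`` over the same columns.
    All regressors are independent unit Gaussians except ``geo_km``, a scaled
    half-normal (distances are non-negative).
    """
    if n_pairs < 20:
        raise ValueError("n_pairs must be >= 20")
    if signal not in ("none", "linear", "nonlinear"):
        raise ValueError(f"unknown signal {signal!r}")
    rng = np.random.default_rng(seed)
    cols = {"geo_km": np.abs(rng.standard_normal(n_pairs)) * 2000.0}
    for v in VARIABLE_ROSTER:
        cols[f"delta_{v}"] = rng.standard_normal(n_pairs)
    X = pd.DataFrame(cols)
    z1, z2, z3 = (X[c].to_numpy() for c in LINEAR_SIGNAL_COLUMNS)
    if signal == "none":
        mean = np.zeros(n_pairs)
    elif signal == "linear":
        b1, b2, b3 = LINEAR_SIGNAL_COEFS
        mean = b1 * z1 + b2 * z2 + b3 * z3
    else:
        mean = np.sin(2.0 * z1) + z2**2 - 1.0 + z3 * z2
    y = mean + (noise_sd * rng.standard_normal(n_pairs) if noise_sd > 0 else 0.0)
    return X, pd.Series(y, name="response")
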