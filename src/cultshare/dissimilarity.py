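"""Hamming dissimilarity, great-circle distance, and the pairwise design table.

The central transformation of the analysis: societies' practice profiles are
compared via Hamming distance (number of differing positions between two
14-position binary vectors), geography via great-circle distance on a sphere,
and every socio-ecological covariate via the absolute pairwise difference
|x_i - x_j|.  For n societies the unordered-pair design table has n(n-1)/2
rows (231 for the 22-society reference inventory).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from cultshare.data import SocietyDataset, ValidationError

__all__ = [
    "EARTH_RADIUS_KM",
    "hamming_distance",
    "hamming_matrix",
    "great_circle_km",
    "build_pairwise_table",
    "pairwise_index",
    "pairwise_hamming_vector",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088


def hamming_distance(u, v) -> int:
    """Number of positions at which two equal-length binary vectors differ."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if not (np.isin(u, (0, 1)).all() and np.isin(v, (0, 1)).all()):
        raise ValueError("inputs must be binary (0/1) vectors")
    return int(np.sum(u != v))


def hamming_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Hamming distances of a binary practice matrix.

    Returns a symmetric, zero-diagonal DataFrame indexed by society name.
    """
    a = m.to_numpy(dtype=int)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("practice matrix must be binary")
    d = (a[:, None, :] != a[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=m.index, columns=m.index)


def great_circle_km(a, b, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Haversine great-circle distance between (lat, lon) points in degrees."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} out of [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} out of [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def pairwise_hamming_vector(m: pd.DataFrame) -> np.ndarray:
    """Upper-triangle Hamming distances as a flat vector (pair order i < j)."""
    d = hamming_matrix(m).to_numpy()
    return d[np.triu_indices_from(d, k=1)].astype(float)


def pairwise_index(names: list[str]) -> list[tuple[int, int]]:
    """Unordered pair indices (i < j) in deterministic lexicographic order."""
    return list(itertools.combinations(range(len(names)), 2))


def build_pairwise_table(dataset: SocietyDataset, m: pd.DataFrame) -> pd.DataFrame:
    """The unordered-pair design table.

    One row per society pair (i < j, input order) with columns ``pair_a``,
    ``pair_b``, ``hamming``, ``geo_km``, then ``delta_<variable>`` (absolute
    covariate difference) for each roster variable.

    Requires coordinates and a complete covariate set; a missing value raises
    a :class:`~cultshare.data.ValidationError` naming society and variable.
    """
    dataset.require_coordinates()
    dataset.require_covariates()
    if list(m.index) != dataset.names:
        raise ValueError("practice matrix rows must match dataset societies")
    dmat = hamming_matrix(m)
    rows = []
    socs = dataset.societies
    for i, j in pairwise_index(dataset.names):
        a, b = socs[i], socs[j]
        row = {
            "pair_a": a.name,
            "pair_b": b.name,
            "hamming": int(dmat.iat[i, j]),
            "geo_km": great_circle_km(
                (a.latitude, a.longitude), (b.latitude, b.longitude)
            ),
        }
        for v in dataset.variable_roster:
            row[f"delta_{v}"] = abs(a.covariates[v] - b.covariates[v])
        rows.append(row)
    return pd.DataFrame(rows)
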