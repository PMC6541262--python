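"""Data model and I/O for society tables.

A *society record* couples a society name with geographic coordinates, the set
of basic food-sharing practices observed in its sharing sequence, and a vector
of socio-ecological covariates.  Fourteen basic practices form a fixed
vocabulary; a society's sharing behaviour is encoded as a 14-position binary
presence/absence vector (the order in which practices occur within the sharing
sequence is deliberately discarded).

The inventory of practices for the 22 reference small-scale societies ships as
an embedded fixture (:func:`builtin_fixture`); coordinates and covariates for
those societies are not bundled and must be joined from a user table or a
synthetic generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "PRACTICE_CODES",
    "PRACTICE_LABELS",
    "VARIABLE_ROSTER",
    "VARIABLE_UNITS",
    "SchemaError",
    "ValidationError",
    "SocietyRecord",
    "SocietyDataset",
    "builtin_fixture",
    "encode_practices",
    "load_society_table",
    "write_society_table",
    "write_results",
    "read_results",
]

#: The 14 basic food-sharing practices, in fixed vocabulary order.  This order
#: is used for every binary practice vector and serialized matrix.
PRACTICE_CODES: tuple[str, ...] = (
    "MM", "TT", "CC", "WD", "OD", "RM", "KS",
    "GS", "NS", "PR", "SD", "DS", "RA", "NN",
)

PRACTICE_LABELS: dict[str, str] = {
    "MM": "Mutualism",
    "TT": "Tolerated Theft",
    "CC": "Communal Consumption",
    "WD": "Women as Distributors",
    "OD": "Other Distributors",
    "RM": "Ranked Mutualism",
    "KS": "Kin Selection",
    "GS": "Group Selection",
    "NS": "Network Selection",
    "PR": "Prestige",
    "SD": "Status Distribution",
    "DS": "Demand Sharing",
    "RA": "Reciprocal Altruism",
    "NN": "Necessity",
}

#: The 21 socio-ecological variables: 11 environmental proxies followed by 10
#: economic ones (resource richness, population pressure and subsistence mix).
VARIABLE_ROSTER: tuple[str, ...] = (
    "annual_mean_temperature",
    "annual_temperature_variance",
    "temperature_constancy",
    "temperature_contingency",
    "annual_mean_precipitation",
    "annual_precipitation_variance",
    "precipitation_constancy",
    "precipitation_contingency",
    "distance_to_coast",
    "elevation",
    "slope",
    "monthly_mean_npp",
    "annual_npp_variance",
    "npp_constancy",
    "npp_contingency",
    "population_size",
    "hunting",
    "gathering",
    "animal_husbandry",
    "fishing",
    "agriculture",
)

VARIABLE_UNITS: dict[str, str] = {
    "annual_mean_temperature": "degC",
    "annual_temperature_variance": "degC^2",
    "temperature_constancy": "dimensionless",
    "temperature_contingency": "dimensionless",
    "annual_mean_precipitation": "mm",
    "annual_precipitation_variance": "mm^2",
    "precipitation_constancy": "dimensionless",
    "precipitation_contingency": "dimensionless",
    "distance_to_coast": "km",
    "elevation": "m",
    "slope": "degrees",
    "monthly_mean_npp": "gC m-2 month-1",
    "annual_npp_variance": "(gC m-2 month-1)^2",
    "npp_constancy": "dimensionless",
    "npp_contingency": "dimensionless",
    "population_size": "individuals",
    "hunting": "percent",
    "gathering": "percent",
    "animal_husbandry": "percent",
    "fishing": "percent",
    "agriculture": "percent",
}

#: Names of the five subsistence-percentage variables (sum to 100 per society).
SUBSISTENCE_VARIABLES: tuple[str, ...] = (
    "hunting", "gathering", "animal_husbandry", "fishing", "agriculture",
)


class SchemaError(ValueError):
    """A table is structurally unusable (missing column, empty file...)."""


class ValidationError(ValueError):
    """A table parses but violates the data model (unknown code, bad range...)."""


@dataclass(frozen=True)
class SocietyRecord:
    """One society: name, optional coordinates, practices, covariates.

    ``latitude``/``longitude`` are decimal degrees and may be ``None`` when the
    record carries only practice information (as the embedded fixture does).
    ``covariates`` maps roster variable names to values; missing variables are
    simply absent keys and are rejected by downstream stages that need them.
    """

    name: str
    latitude: float | None = None
    longitude: float | None = None
    practices: frozenset[str] = field(default_factory=frozenset)
    covariates: dict[str, float] = field(default_factory=dict)
    ehraf_name: str | None = None

    def __post_init__(self) -> None:
        if not self.practices:
            raise ValidationError(f"society {self.name!r}: empty practice set")
        unknown = set(self.practices) - set(PRACTICE_CODES)
        if unknown:
            raise ValidationError(
                f"society {self.name!r}: unknown practice code(s) {sorted(unknown)}"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"society {self.name!r}: latitude {self.latitude} out of [-90, 90]"
            )
        if self.longitude is not None and not -180.0 < self.longitude <= 180.0:
            raise ValidationError(
                f"society {self.name!r}: longitude {self.longitude} out of (-180, 180]"
            )
        bad_vars = set(self.covariates) - set(VARIABLE_ROSTER)
        if bad_vars:
            raise ValidationError(
                f"society {self.name!r}: covariate(s) {sorted(bad_vars)} not in roster"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True)
class SocietyDataset:
    """An ordered collection of societies plus the covariate roster."""

    societies: tuple[SocietyRecord, ...]
    variable_roster: tuple[str, ...] = VARIABLE_ROSTER

    def __post_init__(self) -> None:
        names = [s.name for s in self.societies]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate society name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.societies)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.societies]

    def society(self, name: str) -> SocietyRecord:
        for s in self.societies:
            if s.name == name:
                return s
        raise KeyError(name)

    def require_covariates(self) -> None:
        """Raise unless every society carries every roster variable."""
        for s in self.societies:
            for v in self.variable_roster:
                value = s.covariates.get(v)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    raise ValidationError(
                        f"society {s.name!r}: missing covariate {v!r}"
                    )

    def require_coordinates(self) -> None:
        for s in self.societies:
            if not s.has_coordinates:
                raise ValidationError(f"society {s.name!r}: missing coordinates")

    def covariate_frame(self) -> pd.DataFrame:
        """Covariates as a (society x variable) DataFrame (NaN where missing)."""
        rows = {
            s.name: {v: s.covariates.get(v, float("nan")) for v in self.variable_roster}
            for s in self.societies
        }
        return pd.DataFrame.from_dict(rows, orient="index").reindex(
            index=self.names, columns=list(self.variable_roster)
        )

    def with_joined(self, other: pd.DataFrame) -> "SocietyDataset":
        """Return a copy with coordinates/covariates joined from a DataFrame.

        ``other`` is indexed by society name and may carry ``latitude``,
        ``longitude``, and any roster variable as columns.  Existing values
        are overwritten by the joined ones.
        """
        new = []
        for s in self.societies:
            if s.name not in other.index:
                new.append(s)
                continue
            row = other.loc[s.name]
            lat = float(row["latitude"]) if "latitude" in other.columns else s.latitude
            lon = float(row["longitude"]) if "longitude" in other.columns else s.longitude
            cov = dict(s.covariates)
            for v in self.variable_roster:
                if v in other.columns and not pd.isna(row[v]):
                    cov[v] = float(row[v])
            new.append(replace(s, latitude=lat, longitude=lon, covariates=cov))
        return SocietyDataset(tuple(new), self.variable_roster)


# ---------------------------------------------------------------------------
# Embedded fixture: practice inventories of the 22 reference societies.
# (name used by D-PLACE, name used in the ethnographic literature, practices
# in the order they were catalogued; only presence matters downstream.)
_FIXTURE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Copper Inuit", "Copper Inuit", "KS NS RA CC"),
    ("Blackfoot", "Blackfoot", "GS OD NN DS"),
    ("Dene", "Chipewyan", "GS WD NS PR RA"),
    ("Crow", "Crow", "RM KS WD TT PR"),
    ("Guaraní", "Guaraní", "KS RA NS SD"),
    ("Naskapi", "Innu Naskapi", "MM NN DS CC PR"),
    ("Kaska", "Kaska", "KS WD TT CC"),
    ("Mescalero", "Mescalero Apache", "RM GS PR"),
    ("Munduruku", "Mundurucú", "NS WD GS RA"),
    ("Assiniboine", "Stoney", "KS GS"),
    ("Warao", "Warao", "KS SD NS CC RA"),
    ("Tucano", "Tukano Makuna", "KS NS RA GS WD"),
    ("Chiricaua", "Eastern Apache", "TT KS NN"),
    ("Shuar", "Jivaro", "SD OD CC PR"),
    ("Western Apache", "Western Apache", "MM DS NS PR"),
    ("Ndyuka", "Ndyuka", "KS WD NS"),
    ("Cubeo", "Cubeo Tukano", "KS WD CC NN"),
    ("Inupiat", "Barrow Inupiat", "RM WD TT NN CC"),
    ("Nivkh", "Nivkh", "MM NN TT"),
    ("Nganasan", "Nganasan", "RM KS WD NS PR RA DS"),
    ("Chukchi", "Chukchee", "RM OD GS SD NN KS"),
    ("Evenk", "Evenks", "GS OD NN"),
)


def builtin_fixture() -> SocietyDataset:
    """The embedded 22-society practice inventory.

    Coordinates and covariates are absent (``None`` / empty); join them from a
    user table (:meth:`SocietyDataset.with_joined`) or a synthetic generator
    before running covariate-dependent stages.
    """
    societies = tuple(
        SocietyRecord(
            name=name,
            practices=frozenset(practices.split()),
            ehraf_name=ehraf,
        )
        for name, ehraf, practices in _FIXTURE_ROWS
    )
    return SocietyDataset(societies)


def encode_practices(dataset: SocietyDataset) -> pd.DataFrame:
    """Binary presence/absence matrix, societies x 14 practice codes.

    Cell (i, k) is 1 iff practice ``k`` is in society ``i``'s sharing sequence;
    column order is the fixed vocabulary order.  The encoding is injective on
    practice sets: two rows coincide iff the sets do.
    """
    data = [
        [1 if code in s.practices else 0 for code in PRACTICE_CODES]
        for s in dataset.societies
    ]
    return pd.DataFrame(data, index=dataset.names, columns=list(PRACTICE_CODES), dtype=int)


# ---------------------------------------------------------------------------
# Tabular I/O

_SEP = {"csv": ",", "tsv": "\t"}


def load_society_table(
    path,
    roster: tuple[str, ...] | list[str] = VARIABLE_ROSTER,
    practice_sep: str = ";",
) -> SocietyDataset:
    """Read a society table (CSV/TSV with header) into a validated dataset.

    Expected columns: ``society``, ``latitude``, ``longitude``, ``practices``
    (codes joined by ``practice_sep`` inside one cell), then any subset of the
    roster variables.  Empty covariate cells become missing values that
    downstream stages reject explicitly.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    required = ["society", "latitude", "longitude", "practices"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    roster = tuple(roster)
    societies = []
    for _, row in frame.iterrows():
        raw = row["practices"]
        if pd.isna(raw) or not str(raw).strip():
            raise ValidationError(f"society {row['society']!r}: empty practice set")
        codes = [c.strip() for c in str(raw).split(practice_sep) if c.strip()]
        if len(codes) != len(set(codes)):
            raise ValidationError(
                f"society {row['society']!r}: duplicate practice code in {codes}"
            )
        cov = {
            v: float(row[v])
            for v in roster
            if v in frame.columns and not pd.isna(row[v])
        }
        societies.append(
            SocietyRecord(
                name=str(row["society"]),
                latitude=None if pd.isna(row["latitude"]) else float(row["latitude"]),
                longitude=None if pd.isna(row["longitude"]) else float(row["longitude"]),
                practices=frozenset(codes),
                covariates=cov,
            )
        )
    return SocietyDataset(tuple(societies), roster)


def write_society_table(dataset: SocietyDataset, path, practice_sep: str = ";") -> None:
    """Write a dataset back to the society-table CSV schema."""
    rows = []
    for s in dataset.societies:
        row = {
            "society": s.name,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "practices": practice_sep.join(
                c for c in PRACTICE_CODES if c in s.practices
            ),
        }
        for v in dataset.variable_roster:
            row[v] = s.covariates.get(v, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a result table; round-trips through :func:`read_results`.

    Floats are written with shortest round-trip repr and read back with the
    round-trip parser, so numeric values survive exactly.
    """
    if format not in _SEP:
        raise ValueError(f"format must be one of {sorted(_SEP)}, got {format!r}")
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, sep=_SEP[format], index=False)


def read_results(path, format: str = "csv") -> pd.DataFrame:
    if format not in _SEP:
        raise ValueError(f"format must be one of {sorted(_SEP)}, got {format!r}")
    return pd.read_csv(path, sep=_SEP[format], float_precision="round_trip")
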