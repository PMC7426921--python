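"""Domain types, validated tabular I/O, and packaged reference tables.

The package analyses insect survey data from log depots (outdoor log
storage yards). Four tabular inputs are handled:

* **survey** — one row per collection event x species: depot, year, month,
  species, family, individual count, life stage, and whether the record
  came from a pheromone trap or from splitting stored wood;
* **registry** — one row per species giving its damage-scale value (0-4,
  Bevan damage classification) and a damage-type label;
* **depots** — depot metadata: province, aspect, altitude, binary
  distance-to-forest class (< 3 km / > 3 km) and forest type at the site;
* **environment** — monthly mean temperature (degC) and relative humidity
  (%) per depot.

All readers validate every row and report *all* malformed rows with their
row numbers in a single :class:`RowValidationError`; nothing is silently
dropped. Numeric fields accept both decimal comma and decimal point on
read; writers always emit a decimal point.

Packaged reference tables (transcriptions of the study's printed tables)
are available through :func:`load_fixture`:

``depots_t1``
    21 log depots in 7 provinces of Northwest Turkey (Western Black Sea
    Region) with aspect, altitude and distance-to-forest class.
``scales_t2``
    The five Bevan damage-scale values (0-4) and their damage-type
    definitions.
``damage_index_t3``
    Per-species Bevan damage indices (%) by province (DU, BO, ZO, BR, KS,
    KR, SI), pooled pheromone-trap column ``P`` and stored-wood column
    ``ST``. Blank cells mean *not detected* and are kept distinct from an
    explicit 0 (detected, zero index — e.g. predator families). Cells
    whose column placement is ambiguous in the source rendering are
    flagged in the ``note`` column (``prov_uncertain`` /
    ``cols_uncertain``) rather than silently guessed.
``distance_t4``
    Frequency, percentage share and printed density for three species
    stratified by depot distance to forest (< 3 km vs > 3 km).
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

__all__ = [
    "LifeStage",
    "Source",
    "Aspect",
    "DistanceClass",
    "ForestType",
    "SurveyRecord",
    "DamageScaleEntry",
    "DepotMetadata",
    "EnvironmentRecord",
    "SchemaError",
    "RowValidationError",
    "DuplicateSpeciesError",
    "read_survey",
    "read_registry",
    "read_depots",
    "read_environment",
    "write_table",
    "load_fixture",
    "default_registry",
    "records_to_frame",
]

SURVEY_COLUMNS = (
    "depot_code", "year", "month", "species", "family",
    "count", "life_stage", "source",
)
REGISTRY_COLUMNS = ("species", "family", "scale_value", "damage_type")
DEPOT_COLUMNS = (
    "depot_code", "province", "aspect", "altitude_m",
    "distance_class", "forest_type",
)
ENVIRONMENT_COLUMNS = ("depot_code", "year", "month", "mean_temp_c", "mean_rh_pct")

FIXTURE_NAMES = ("depots_t1", "scales_t2", "damage_index_t3", "distance_t4")

PROVINCES = ("DU", "BO", "ZO", "BR", "KS", "KR", "SI")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class LifeStage(str, enum.Enum):
    larva = "larva"
    pupa = "pupa"
    adult = "adult"
    unknown = "unknown"


class Source(str, enum.Enum):
    """How the insects were obtained: funnel pheromone trap, or collected
    while splitting stored logs."""

    pheromone_trap = "pheromone_trap"
    stored_wood = "stored_wood"


class Aspect(str, enum.Enum):
    N = "N"
    NE = "NE"
    E = "E"
    SE = "SE"
    S = "S"
    SW = "SW"
    W = "W"
    NW = "NW"
    F = "F"  # flat site, no aspect


class DistanceClass(str, enum.Enum):
    """Binary depot distance to the nearest forested area, as surveyed."""

    lt_3km = "lt_3km"
    gt_3km = "gt_3km"


class ForestType(str, enum.Enum):
    coniferous = "coniferous"
    deciduous = "deciduous"
    none = "none"


class SurveyRecord(BaseModel):
    """One detection event: a species collected at a depot in a given
    month, with the number of individuals."""

    depot_code: str
    year: int
    month: int = Field(ge=1, le=12)
    species: str
    family: str
    count: int = Field(ge=0)
    life_stage: LifeStage = LifeStage.unknown
    source: Source

    @field_validator("depot_code", "species", "family")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        v = v.strip()
        if not v:
            raise ValueError("must be non-empty")
        return v


class DamageScaleEntry(BaseModel):
    """Species -> Bevan damage-scale value (0-4) with a damage-type label.

    Scale 0 marks predators of bark insects and fungus feeders; scale 4
    marks species generating excessive economic damage to wood.
    """

    species: str
    family: str
    scale_value: int = Field(ge=0, le=4)
    damage_type: str = ""


class DepotMetadata(BaseModel):
    depot_code: str
    province: str
    aspect: Aspect
    altitude_m: float = Field(ge=0)
    distance_class: DistanceClass
    forest_type: ForestType = ForestType.none


class EnvironmentRecord(BaseModel):
    """Monthly mean temperature and relative humidity at one depot."""

    depot_code: str
    year: int
    month: int = Field(ge=1, le=12)
    mean_temp_c: float
    mean_rh_pct: float = Field(ge=0, le=100)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """The file header is missing one or more required columns."""

    def __init__(self, missing: Sequence[str], path: object = None):
        self.missing = list(missing)
        where = f" in {path}" if path is not None else ""
        super().__init__(f"missing required column(s){where}: {', '.join(self.missing)}")


class RowValidationError(ValueError):
    """One or more data rows failed validation.

    ``errors`` is a list of ``(row_number, message)`` pairs; row numbers
    are 1-based data-row positions (header not counted). Every bad row is
    reported — validation never stops at the first failure.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.errors[:20])
        extra = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{extra}")


class DuplicateSpeciesError(ValueError):
    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = sorted(set(duplicates))
        super().__init__("duplicate species in registry: " + ", ".join(self.duplicates))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _normalise_decimal(value: object) -> object:
    # survey files from the region use decimal commas; normalise on read
    if isinstance(value, str):
        return value.strip().replace(",", ".")
    return value


def _read_csv(path: str | Path, required: Sequence[str],
              schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(missing, path)
    return df


def _validate_rows(df: pd.DataFrame, model: type[BaseModel]) -> list[BaseModel]:
    out: list[BaseModel] = []
    errors: list[tuple[int, str]] = []
    fields = list(model.model_fields)
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        raw = {f: _normalise_decimal(getattr(row, f)) for f in fields if hasattr(row, f)}
        try:
            out.append(model.model_validate(raw))
        except ValidationError as exc:
            msgs = "; ".join(
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
            )
            errors.append((pos, msgs))
    if errors:
        raise RowValidationError(errors)
    return out


def read_survey(path: str | Path,
                schema: Mapping[str, str] | None = None) -> list[SurveyRecord]:
    """Read a survey CSV into validated :class:`SurveyRecord` objects.

    Parameters
    ----------
    path
        CSV with header ``depot_code,year,month,species,family,count,
        life_stage,source``.
    schema
        Optional mapping from the file's column names to the canonical
        ones, for files with different headers.

    Raises
    ------
    SchemaError
        If a required column is absent (the error names it).
    RowValidationError
        Listing every malformed row with its row number.
    """
    df = _read_csv(path, SURVEY_COLUMNS, schema)
    return _validate_rows(df, SurveyRecord)  # type: ignore[return-value]


def read_registry(path: str | Path) -> list[DamageScaleEntry]:
    """Read a species damage-scale registry; each species must appear once."""
    df = _read_csv(path, REGISTRY_COLUMNS)
    entries = _validate_rows(df, DamageScaleEntry)
    dup = df["species"].str.strip()[df["species"].str.strip().duplicated()].tolist()
    if dup:
        raise DuplicateSpeciesError(dup)
    return entries  # type: ignore[return-value]


def read_depots(path: str | Path) -> list[DepotMetadata]:
    df = _read_csv(path, DEPOT_COLUMNS)
    return _validate_rows(df, DepotMetadata)  # type: ignore[return-value]


def read_environment(path: str | Path) -> list[EnvironmentRecord]:
    df = _read_csv(path, ENVIRONMENT_COLUMNS)
    return _validate_rows(df, EnvironmentRecord)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with point decimal separator.

    Round-trip contract: reading the file back yields identical values at
    the written precision. Floats are written at full repr precision;
    presentation rounding is the caller's choice.
    """
    if table is None:
        raise ValueError("table is None")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def records_to_frame(records: Iterable[BaseModel]) -> pd.DataFrame:
    """Convenience: list of pydantic records -> DataFrame (enum values as str)."""
    rows = [r.model_dump() for r in records]
    df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, enum.Enum)).any():
            df[col] = df[col].map(lambda v: v.value if isinstance(v, enum.Enum) else v)
    return df


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("bevan_severity.data").joinpath(filename)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables (see module docstring).

    ``damage_index_t3`` uses ``NaN`` for *not detected* (blank in the
    source) as opposed to an explicit ``0.0`` (detected, zero index).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    with resources.as_file(_data_path(f"{name}.csv")) as p:
        if name == "damage_index_t3":
            df = pd.read_csv(p, dtype={"note": str})
            df["note"] = df["note"].fillna("")
            return df
        return pd.read_csv(p)


def default_registry() -> list[DamageScaleEntry]:
    """Reconstructed species damage-scale registry.

    The study never prints a per-species scale column, so the registry is
    rebuilt as data: every species of the transcribed damage-index table
    inherits the scale of its family (``data/family_scales.csv``), which
    encodes the damage-type semantics of the five-point scale — e.g.
    wood-boring Cerambycidae/Buprestidae/Anobiidae at 4, bark-breeding
    Scolytinae at 1, stored-wood tunnellers (Tenebrionidae, Elateridae)
    at 2, and predators/fungus feeders (Cleridae, Trogositidae,
    Cantharidae, ...) at 0. Users with better knowledge of a species can
    supply their own registry CSV instead.
    """
    with resources.as_file(_data_path("family_scales.csv")) as p:
        fam = pd.read_csv(p).set_index("family")
    t3 = load_fixture("damage_index_t3")
    entries = []
    for _, row in t3.iterrows():
        f = row["family"]
        entries.append(DamageScaleEntry(
            species=row["species"], family=f,
            scale_value=int(fam.loc[f, "scale_value"]),
            damage_type=str(fam.loc[f, "damage_type"]),
        ))
    return entries
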