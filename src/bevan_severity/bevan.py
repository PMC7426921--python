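"""Bevan damage-index computation.

The Bevan damage classification assigns each species a damage-scale value
s in {0..4} by damage type; the damage index of species *i* within a
group of survey records is the normalised percentage

    index_i = 100 * f_i * s_i / sum_j f_j * s_j

where f_i is the *frequency* of the species: the number of distinct
collection events (depot x year x month) in which it was detected —
appearances over time, not summed individuals. Indices within one
normalisation group therefore sum to 100 whenever any f*s product is
positive. The natural grouping mirrors the study's reporting: one
percentage scale per (region x trap source) — per-province columns, a
pooled pheromone column, and a stored-wood column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .survey_io import DamageScaleEntry, DepotMetadata, SurveyRecord

__all__ = [
    "FrequencyTable",
    "DamageIndexTable",
    "DegenerateGroupError",
    "MissingScaleError",
    "tabulate_frequency",
    "damage_index",
    "rank_species",
    "count_species",
    "round_half_up",
]

SURVEY_FIELDS = frozenset(SurveyRecord.model_fields)
DEPOT_FIELDS = frozenset(DepotMetadata.model_fields)


class MissingScaleError(KeyError):
    """A species in the frequency table has no registry entry."""

    def __init__(self, species: Sequence[str]):
        self.species = sorted(species)
        super().__init__("species missing from registry: " + ", ".join(self.species))


class DegenerateGroupError(ValueError):
    """All frequency x scale products are zero: every index is undefined."""

    def __init__(self, group: Hashable):
        self.group = group
        super().__init__(f"group {group!r}: total damage weight is 0, indices undefined")


@dataclass
class FrequencyTable:
    """Per-group species frequencies (distinct detection events)."""

    group: Hashable
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: f for s, f in self.entries.items() if f < 0}
        if bad:
            raise ValueError(f"negative frequencies: {bad}")


@dataclass
class DamageIndexTable:
    """Per-group Bevan indices (%). ``denominator`` is sum(f*s) over the
    group; ``degenerate`` marks an all-zero denominator, in which case
    ``entries`` is empty rather than silently zero."""

    group: Hashable
    entries: dict[str, float] = field(default_factory=dict)
    denominator: float = 0.0
    degenerate: bool = False


def _group_key(record: SurveyRecord, depot: DepotMetadata | None,
               group_by: Sequence[str]) -> Hashable:
    parts = []
    for name in group_by:
        if name in SURVEY_FIELDS:
            parts.append(getattr(record, name))
        elif name in DEPOT_FIELDS:
            if depot is None:
                raise KeyError(
                    f"grouping field {name!r} needs depot metadata, none given for "
                    f"depot {record.depot_code!r}")
            parts.append(getattr(depot, name))
        else:
            raise KeyError(f"unknown grouping field {name!r}")
    vals = [p.value if hasattr(p, "value") else p for p in parts]
    return tuple(vals) if len(vals) != 1 else vals[0]


def tabulate_frequency(records: Iterable[SurveyRecord],
                       group_by: Sequence[str] | None = None,
                       depots: Iterable[DepotMetadata] | None = None,
                       ) -> list[FrequencyTable]:
    """Tabulate species frequencies per group.

    Frequency is the number of distinct (depot, year, month) collection
    events in which the species was detected with count >= 1; individuals
    are never summed. ``group_by`` names fields of ``SurveyRecord`` (e.g.
    ``source``) and/or ``DepotMetadata`` (e.g. ``province``,
    ``distance_class``; requires ``depots``). ``None`` pools everything
    into a single group keyed ``"all"``.

    Raises ``KeyError`` for an unknown grouping field and for depot codes
    without metadata when depot fields are requested.
    """
    group_by = list(group_by or [])
    for name in group_by:
        if name not in SURVEY_FIELDS and name not in DEPOT_FIELDS:
            raise KeyError(f"unknown grouping field {name!r}")
    depot_map = {d.depot_code: d for d in depots} if depots is not None else {}

    seen: dict[Hashable, dict[str, set]] = {}
    for rec in records:
        if rec.count < 1:
            continue
        depot = depot_map.get(rec.depot_code)
        if depot is None and any(n in DEPOT_FIELDS for n in group_by):
            raise KeyError(f"no depot metadata for depot {rec.depot_code!r}")
        key = _group_key(rec, depot, group_by) if group_by else "all"
        events = seen.setdefault(key, {}).setdefault(rec.species, set())
        events.add((rec.depot_code, rec.year, rec.month))

    tables = [
        FrequencyTable(group=key,
                       entries={sp: len(ev) for sp, ev in sorted(per.items())})
        for key, per in seen.items()
    ]
    tables.sort(key=lambda t: str(t.group))
    return tables


def damage_index(freq: FrequencyTable,
                 scales: Iterable[DamageScaleEntry] | Mapping[str, int],
                 ) -> DamageIndexTable:
    """Compute Bevan damage indices for one frequency group.

    Every species in ``freq`` must have a scale entry
    (:class:`MissingScaleError` otherwise). If all f*s products are zero
    the result is returned with ``degenerate=True`` and no entries —
    undefined indices are flagged, never emitted as zeros. Full precision
    is kept internally; round only at presentation (:func:`round_half_up`).
    """
    if isinstance(scales, Mapping):
        scale_map = dict(scales)
    else:
        scale_map = {e.species: e.scale_value for e in scales}
    missing = [s for s in freq.entries if s not in scale_map]
    if missing:
        raise MissingScaleError(missing)

    weights = {s: f * scale_map[s] for s, f in freq.entries.items()}
    denom = float(sum(weights.values()))
    if denom == 0.0:
        return DamageIndexTable(group=freq.group, degenerate=True)
    entries = {s: 100.0 * w / denom for s, w in weights.items()}
    return DamageIndexTable(group=freq.group, entries=entries, denominator=denom)


def rank_species(table: DamageIndexTable | Mapping[str, float],
                 top_n: int) -> list[tuple[str, float]]:
    """Top-n species by damage index, descending; ties broken by species
    name ascending so the ranking is deterministic. ``top_n`` larger than
    the table returns the full ranking."""
    if top_n <= 0:
        raise ValueError(f"top_n must be positive, got {top_n}")
    if isinstance(table, DamageIndexTable):
        if table.degenerate:
            raise DegenerateGroupError(table.group)
        entries = table.entries
    else:
        entries = dict(table)
    ranked = sorted(entries.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def count_species(records_or_table: Iterable[SurveyRecord] | pd.DataFrame,
                  family: str) -> int:
    """Number of distinct species assigned to ``family`` in survey records
    or in any table with ``species`` and ``family`` columns. Unknown
    family -> 0."""
    if not family:
        raise ValueError("family must be non-empty")
    if isinstance(records_or_table, pd.DataFrame):
        df = records_or_table
        return int(df.loc[df["family"] == family, "species"].nunique())
    return len({r.species for r in records_or_table if r.family == family})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Presentation rounding, half away from zero (table style: 0.25 -> 0.3)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
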