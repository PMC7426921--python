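"""Monthly phenology series and correlation with environmental factors.

For a beetle family (typically Cerambycidae or Buprestidae) the module
builds aligned monthly series over the trapping season — insect
frequency (distinct detection events), species number (distinct species)
and insect density — together with mean temperature and relative
humidity, and correlates every pair with the sample Pearson coefficient.
The two-sided p-value comes from the t transform with n-2 degrees of
freedom. Correlation strength is labelled on |r| with the survey
convention: 0 none, up to ~0.29 low, ~0.30-0.70 intermediate,
~0.71-0.99 high, beyond that excellent; the printed bins leave gaps, so
the implementation uses the half-open cutpoints 0, 0.295, 0.705, 0.995
(the two-decimal rounding boundaries), which makes classification total.
Negative coefficients are classified by magnitude; the sign stays in r.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .density import DEFAULT_SEASON_YEARS, insect_density
from .survey_io import EnvironmentRecord, SurveyRecord

__all__ = [
    "Strength",
    "CorrelationResult",
    "MonthlySeries",
    "monthly_series",
    "pearson_with_p",
    "classify_strength",
    "correlation_matrix",
    "correlation_frame",
]

SERIES_VARIABLES = ("temperature", "rh", "frequency", "species_number", "density")


class Strength(str, enum.Enum):
    none = "none"
    low = "low"
    intermediate = "intermediate"
    high = "high"
    excellent = "excellent"


@dataclass
class CorrelationResult:
    """Pearson r between two monthly variables, with two-sided p.

    ``defined`` is False when the coefficient does not exist (fewer than
    3 points or a zero-variance vector); r and p are then None rather
    than a silent number substitute.
    """

    var_x: str
    var_y: str
    r: float | None
    p: float | None
    n: int
    strength: Strength | None
    defined: bool = True

    @property
    def significant_0p01(self) -> bool:
        return self.defined and self.p is not None and self.p < 0.01

    @property
    def significant_0p05(self) -> bool:
        return self.defined and self.p is not None and self.p < 0.05


@dataclass
class MonthlySeries:
    """Aligned per-month vectors for one family. ``months`` holds
    (year, month) keys; with pooled years the year slot is 0."""

    family: str
    months: list[tuple[int, int]]
    frequency: np.ndarray = field(default_factory=lambda: np.array([]))
    species_number: np.ndarray = field(default_factory=lambda: np.array([]))
    density: np.ndarray = field(default_factory=lambda: np.array([]))
    temperature: np.ndarray = field(default_factory=lambda: np.array([]))
    rh: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        n = len(self.months)
        for name in ("frequency", "species_number", "density", "temperature", "rh"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size != n:
                raise ValueError(f"{name} has length {v.size}, expected {n}")
            setattr(self, name, v)

    def variable(self, name: str) -> np.ndarray:
        if name not in SERIES_VARIABLES:
            raise KeyError(f"unknown series variable {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": [y for y, _ in self.months],
            "month": [m for _, m in self.months],
            "frequency": self.frequency.astype(int),
            "species_number": self.species_number.astype(int),
            "density": self.density,
            "temperature": self.temperature,
            "rh": self.rh,
        })


def monthly_series(records: Iterable[SurveyRecord],
                   env: Iterable[EnvironmentRecord],
                   family: str,
                   area_map: Mapping[str, float] | None = None,
                   duration: float = DEFAULT_SEASON_YEARS / 7.0,
                   pool_years: bool = False) -> MonthlySeries:
    """Build the aligned monthly series for one family.

    Months covered are all (year, month) pairs present in ``env``; months
    with records but no environment data raise ``KeyError`` naming the
    month. Frequency counts distinct (species, depot, year, month)
    detection events; species number counts distinct species; density is
    (pooled monthly individuals / total area) / ``duration``, with
    ``duration`` defaulting to one month of the April-October season in
    years. Temperature and RH average the environment records of the
    depots contributing to the survey (all env depots if the family was
    never caught). With ``pool_years`` the calendar months of both years
    are merged (the figure-style view); the default keeps each
    (year, month) as its own point.
    """
    records = [r for r in records if r.family == family and r.count >= 1]
    env = list(env)
    if not env:
        raise ValueError("no environment records given")
    survey_depots = {r.depot_code for r in records}
    env_df = pd.DataFrame([e.model_dump() for e in env])
    if survey_depots:
        env_sub = env_df[env_df["depot_code"].isin(survey_depots)]
        if env_sub.empty:
            env_sub = env_df
    else:
        env_sub = env_df

    env_months = {(int(y), int(m)) for y, m in zip(env_df["year"], env_df["month"])}
    rec_months = {(r.year, r.month) for r in records}
    orphans = sorted(rec_months - env_months)
    if orphans:
        raise KeyError(
            "months with survey records but no environment data: "
            + ", ".join(f"{y}-{m:02d}" for y, m in orphans))

    def month_key(year: int, month: int) -> tuple[int, int]:
        return (0, month) if pool_years else (year, month)

    months = sorted({month_key(y, m) for y, m in env_months})
    idx = {k: i for i, k in enumerate(months)}

    freq = np.zeros(len(months))
    nind = np.zeros(len(months))
    species: list[set] = [set() for _ in months]
    events: list[set] = [set() for _ in months]
    for r in records:
        i = idx[month_key(r.year, r.month)]
        events[i].add((r.species, r.depot_code, r.year, r.month))
        species[i].add(r.species)
        nind[i] += r.count
    freq = np.array([len(e) for e in events], dtype=float)
    sp_no = np.array([len(s) for s in species], dtype=float)

    if area_map is None:
        area_map = {code: 1.0 for code in env_df["depot_code"].unique()}
    total_area = float(sum(area_map.values()))
    dens = np.array([insect_density(n, total_area, duration) for n in nind])

    env_sub = env_sub.copy()
    env_sub["key"] = [month_key(int(y), int(m))
                      for y, m in zip(env_sub["year"], env_sub["month"])]
    means = env_sub.groupby("key")[["mean_temp_c", "mean_rh_pct"]].mean()
    temp = np.array([means.loc[[k], "mean_temp_c"].iloc[0] for k in months])
    rh = np.array([means.loc[[k], "mean_rh_pct"].iloc[0] for k in months])

    return MonthlySeries(family=family, months=months, frequency=freq,
                         species_number=sp_no, density=dens,
                         temperature=temp, rh=rh)


def pearson_with_p(x: Sequence[float], y: Sequence[float],
                   var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with two-sided p (t transform, n-2 df).

    Fewer than 3 points or a zero-variance vector yields a flagged
    undefined result (``defined=False``), never NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = int(x.size)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(var_x=var_x, var_y=var_y, r=None, p=None,
                                 n=n, strength=None, defined=False)
    res = stats.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(var_x=var_x, var_y=var_y, r=r,
                             p=float(res.pvalue), n=n,
                             strength=classify_strength(r))


def classify_strength(r: float) -> Strength:
    """Label |r|: 0 none; (0, 0.295] low; (0.295, 0.705] intermediate;
    (0.705, 0.995] high; above excellent. Total on [-1, 1]."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    a = min(a, 1.0)
    if a == 0.0:
        return Strength.none
    if a <= 0.295:
        return Strength.low
    if a <= 0.705:
        return Strength.intermediate
    if a <= 0.995:
        return Strength.high
    return Strength.excellent


def correlation_matrix(series: MonthlySeries) -> list[CorrelationResult]:
    """All pairwise correlations among temperature, RH, frequency,
    species number and density, including the unit diagonal. Results are
    symmetric: (x, y) and (y, x) are both emitted with identical r."""
    if len(series.months) < 3:
        raise ValueError("need at least 3 months for a correlation matrix")
    out: list[CorrelationResult] = []
    for vx, vy in itertools.product(SERIES_VARIABLES, repeat=2):
        if vx == vy:
            out.append(CorrelationResult(var_x=vx, var_y=vy, r=1.0, p=0.0,
                                         n=len(series.months),
                                         strength=Strength.excellent))
        else:
            out.append(pearson_with_p(series.variable(vx), series.variable(vy),
                                      var_x=vx, var_y=vy))
    return out


def correlation_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"var_x": c.var_x, "var_y": c.var_y, "r": c.r, "p": c.p, "n": c.n,
         "strength": c.strength.value if c.strength else "undefined",
         "significant_0p01": c.significant_0p01,
         "significant_0p05": c.significant_0p05}
        for c in results
    ])
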