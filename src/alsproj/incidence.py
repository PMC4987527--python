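"""Incidence schedules and disease-duration tables.

An :class:`IncidenceSchedule` carries the age-specific incidence of ALS (new
cases per 100,000 person-years) for one region and one sex, together with the
catchment size of the source study (used later as a pooling weight) and the
case definition (ALS under the El Escorial criteria, or the broader motor
neuron disease class used by some older studies — carried as metadata, never
used to adjust rates).  A :class:`DurationModel` holds the median disease
duration in years for one region; under the stationary approximation,
prevalence = incidence x median duration.

CSV dialects
------------
Incidence: ``region,sex,age_lo,age_hi,rate_per_100k,study_population,
case_definition`` with optional ``period_start,period_end``; ``age_hi`` blank
or '+'-suffixed marks an open-ended band.  Durations:
``region,median_duration_years``.  UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .agebands import AgeBand, validate_band_sequence
from .errors import FormatError, ValidationError

SEXES = ("male", "female")
CASE_DEFINITIONS = ("ALS", "MND")

_INCIDENCE_COLUMNS = [
    "region",
    "sex",
    "age_lo",
    "age_hi",
    "rate_per_100k",
    "study_population",
    "case_definition",
]
_DURATION_COLUMNS = ["region", "median_duration_years"]


@dataclass(frozen=True)
class IncidenceSchedule:
    """Age-specific incidence for one (region, sex) stratum.

    entries are (band, rate per 100,000 person-years) pairs, bands ascending
    and non-overlapping, with at most one open-ended band (the oldest).
    """

    region_id: str
    sex: str
    entries: tuple[tuple[AgeBand, float], ...]
    study_population: float
    case_definition: str = "ALS"
    study_period: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ctx = f"{self.region_id}/{self.sex}"
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r} ({ctx})")
        if self.case_definition not in CASE_DEFINITIONS:
            raise ValidationError(
                f"case_definition must be one of {CASE_DEFINITIONS}, "
                f"got {self.case_definition!r} ({ctx})"
            )
        if not (self.study_population > 0 and math.isfinite(self.study_population)):
            raise ValidationError(f"study_population must be > 0 ({ctx})")
        for band, rate in self.entries:
            if not (rate >= 0 and math.isfinite(rate)):
                raise ValidationError(f"negative or non-finite rate in band {band.label} ({ctx})")
        validate_band_sequence([b for b, _ in self.entries], context=ctx)

    @property
    def bands(self) -> tuple[AgeBand, ...]:
        return tuple(b for b, _ in self.entries)

    def rate(self, band: AgeBand) -> float:
        for b, r in self.entries:
            if b == band:
                return r
        raise KeyError(band)


@dataclass(frozen=True)
class DurationModel:
    """Median ALS disease duration, in years, for one region."""

    region_id: str
    median_duration: float

    def __post_init__(self) -> None:
        if not (self.median_duration > 0 and math.isfinite(self.median_duration)):
            raise ValidationError(
                f"median duration must be positive and finite, got "
                f"{self.median_duration} ({self.region_id})"
            )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_incidence_table(path) -> list[IncidenceSchedule]:
    """Read an incidence CSV into one validated schedule per (region, sex).

    Bands are normalised to ascending order; overlapping bands, negative
    rates and unknown sexes raise :class:`ValidationError` naming the
    offending stratum.
    """
    df = pd.read_csv(path, dtype={"age_hi": "string"}, float_precision="round_trip")
    _require_columns(df, _INCIDENCE_COLUMNS, path)
    has_period = "period_start" in df.columns and "period_end" in df.columns
    schedules: list[IncidenceSchedule] = []
    for (region, sex), group in df.groupby(["region", "sex"], sort=True):
        entries = []
        for _, row in group.iterrows():
            hi = row["age_hi"]
            band = AgeBand.from_bounds(row["age_lo"], None if pd.isna(hi) else hi)
            entries.append((band, float(row["rate_per_100k"])))
        entries.sort(key=lambda e: e[0].lower)
        meta = group.iloc[0]
        period = None
        if has_period and not pd.isna(meta["period_start"]):
            period = (int(meta["period_start"]), int(meta["period_end"]))
        pops = set(group["study_population"].astype(float))
        if len(pops) != 1:
            raise ValidationError(
                f"inconsistent study_population within {region}/{sex}: {sorted(pops)}"
            )
        schedules.append(
            IncidenceSchedule(
                region_id=str(region),
                sex=str(sex),
                entries=tuple(entries),
                study_population=float(meta["study_population"]),
                case_definition=str(meta["case_definition"]),
                study_period=period,
            )
        )
    return schedules


def write_incidence_table(schedules: Sequence[IncidenceSchedule], path) -> None:
    """Write schedules to CSV such that :func:`read_incidence_table` inverts it."""
    rows = []
    for s in schedules:
        for band, rate in s.entries:
            rows.append(
                {
                    "region": s.region_id,
                    "sex": s.sex,
                    "age_lo": band.lower,
                    "age_hi": "" if band.upper is None else band.upper,
                    "rate_per_100k": rate,
                    "study_population": s.study_population,
                    "case_definition": s.case_definition,
                    "period_start": "" if s.study_period is None else s.study_period[0],
                    "period_end": "" if s.study_period is None else s.study_period[1],
                }
            )
    df = pd.DataFrame(rows, columns=_INCIDENCE_COLUMNS + ["period_start", "period_end"])
    df.to_csv(path, index=False)


def read_durations(path) -> list[DurationModel]:
    """Read a ``region,median_duration_years`` CSV into validated models."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _DURATION_COLUMNS, path)
    return [
        DurationModel(region_id=str(row["region"]), median_duration=float(row["median_duration_years"]))
        for _, row in df.iterrows()
    ]


def write_durations(durations: Sequence[DurationModel], path) -> None:
    df = pd.DataFrame(
        [{"region": d.region_id, "median_duration_years": d.median_duration} for d in durations],
        columns=_DURATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def durations_by_region(durations: Sequence[DurationModel]) -> dict[str, DurationModel]:
    out: dict[str, DurationModel] = {}
    for d in durations:
        if d.region_id in out:
            raise ValidationError(f"duplicate duration entry for region {d.region_id}")
        out[d.region_id] = d
    return out
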