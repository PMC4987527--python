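"""Expected ALS case counts per region, year and sex, plus trend analytics.

The central quantity is the stationary prevalence approximation applied
band-wise:

    cases(sex, band) = rate(sex, band) / 100,000
                       x population(sex, band)
                       x median disease duration (years)

with incidence held constant across calendar years (ALS incidence is
observed to be stable over time), so a 2015 and a 2040 projection for the
same region differ only through the population pyramid.  Everything is
computed unrounded; rounding (half away from zero) belongs to report
formatting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .agebands import OPEN_BAND_NOMINAL_WIDTH, STANDARD_GRID, AgeBand
from .errors import ConfigError, DomainError, ValidationError
from .incidence import DurationModel
from .population import HarmonizedRates, PopulationPyramid

CONTINENTS = ("Africa", "NorthAmerica", "SouthAmerica", "Asia", "Europe", "Oceania")
DEVELOPMENT_LEVELS = ("developed", "developing")


@dataclass(frozen=True)
class CaseProjection:
    """Expected case counts for one region-year, by sex and by (sex, band).

    Counts are real-valued: an expectation, not an integer census.
    """

    region_id: str
    year: int
    cases_by_band: Mapping[tuple[str, AgeBand], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases_by_band", dict(self.cases_by_band))
        for key, v in self.cases_by_band.items():
            if not (v >= 0 and math.isfinite(v)):
                raise ValidationError(f"negative case count {v} for {key} in {self.region_id}")

    @property
    def cases_by_sex(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (sex, _), v in self.cases_by_band.items():
            out[sex] = out.get(sex, 0.0) + v
        return out

    @property
    def total(self) -> float:
        return sum(self.cases_by_band.values())


@dataclass(frozen=True)
class RegionHierarchy:
    """Country -> continent and country -> developed/developing lookups."""

    continent_of: Mapping[str, str]
    development_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "continent_of", dict(self.continent_of))
        object.__setattr__(self, "development_of", dict(self.development_of))
        for region, cont in self.continent_of.items():
            if cont not in CONTINENTS:
                raise ValidationError(f"unknown continent {cont!r} for region {region}")
        for region, dev in self.development_of.items():
            if dev not in DEVELOPMENT_LEVELS:
                raise ValidationError(f"unknown development level {dev!r} for region {region}")

    def classify(self, region: str, by: str) -> str:
        table = {"continent": self.continent_of, "development": self.development_of}[by]
        if region not in table:
            raise ConfigError(f"region {region!r} is not classified by {by}")
        return table[region]

    @classmethod
    def from_csv(cls, path) -> "RegionHierarchy":
        df = pd.read_csv(path)
        for col in ("region", "continent", "development"):
            if col not in df.columns:
                from .errors import FormatError

                raise FormatError(f"{path}: missing column(s) {col}")
        return cls(
            continent_of={str(r["region"]): str(r["continent"]) for _, r in df.iterrows()},
            development_of={str(r["region"]): str(r["development"]) for _, r in df.iterrows()},
        )


class GroupTotal(NamedTuple):
    cases: float
    share: float


def project_cases(
    rates: Mapping[str, HarmonizedRates],
    pyramid: PopulationPyramid,
    duration: DurationModel,
) -> CaseProjection:
    """Apply the incidence x population x duration product band-wise.

    ``rates`` maps sex to that sex's harmonized schedule; all three inputs
    must refer to the same region.  No rounding is applied.
    """
    for sex, hr in rates.items():
        if hr.region_id != pyramid.region_id:
            raise ConfigError(
                f"rates for {hr.region_id!r} applied to pyramid {pyramid.region_id!r}"
            )
        if hr.sex != sex:
            raise ConfigError(f"rates keyed {sex!r} but labelled {hr.sex!r}")
    if duration.region_id != pyramid.region_id:
        raise ConfigError(
            f"duration for {duration.region_id!r} applied to pyramid {pyramid.region_id!r}"
        )
    cases: dict[tuple[str, AgeBand], float] = {}
    for sex, hr in rates.items():
        pop = pyramid.band_counts(sex)
        for band in STANDARD_GRID:
            cases[(sex, band)] = (
                hr.rates[band] / 100_000.0 * pop[band] * duration.median_duration
            )
    return CaseProjection(region_id=pyramid.region_id, year=pyramid.year, cases_by_band=cases)


def percent_change(before: float, after: float) -> float:
    """Unrounded percent change 100 x (after - before) / before."""
    if not (before > 0 and math.isfinite(before)):
        raise DomainError(f"baseline must be positive, got {before}")
    if not (after >= 0 and math.isfinite(after)):
        raise DomainError(f"projected value must be non-negative, got {after}")
    return 100.0 * (after - before) / before


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in report tables)."""
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def aggregate(
    projections: Sequence[CaseProjection],
    hierarchy: RegionHierarchy,
    by: str = "development",
) -> dict[str, dict[int, GroupTotal]]:
    """Roll projections up to developed/developing, continent or grand totals.

    Returns group -> year -> (total cases, share of the all-group total for
    that year).  Totals are sums of unrounded per-region counts; shares sum
    to 1 per year.
    """
    if by not in ("development", "continent", "all"):
        raise ConfigError(f"grouping key must be development, continent or all, got {by!r}")
    totals: dict[str, dict[int, float]] = {}
    year_totals: dict[int, float] = {}
    for proj in projections:
        group = "all" if by == "all" else hierarchy.classify(proj.region_id, by)
        totals.setdefault(group, {}).setdefault(proj.year, 0.0)
        totals[group][proj.year] += proj.total
        year_totals[proj.year] = year_totals.get(proj.year, 0.0) + proj.total
    return {
        group: {
            year: GroupTotal(cases=v, share=v / year_totals[year])
            for year, v in sorted(years.items())
        }
        for group, years in sorted(totals.items())
    }


def median_population_age(pyramid: PopulationPyramid) -> float:
    """Median age of a pyramid, interpolated uniformly within the band that
    holds the 50th percentile; the open 100+ band counts as 5 years wide."""
    total = pyramid.total()
    if total <= 0:
        raise DomainError(f"pyramid {pyramid.region_id}/{pyramid.year} has no population")
    band_sums = {
        band: sum(pyramid.counts.get((sex, band), 0.0) for sex in pyramid.sexes)
        for band in STANDARD_GRID
    }
    half = total / 2.0
    cum = 0.0
    for band in STANDARD_GRID:
        n = band_sums[band]
        if cum + n >= half:
            if n == 0:
                return float(band.lower)
            width = band.width if band.upper is not None else OPEN_BAND_NOMINAL_WIDTH
            return band.lower + (half - cum) / n * width
        cum += n
    return 100.0 + OPEN_BAND_NOMINAL_WIDTH  # only reachable through rounding noise


def ageing_correlation(
    case_changes: Mapping[str, float],
    age_changes: Mapping[str, float],
) -> float:
    """Pearson correlation between per-region percent change in case numbers
    and percent change in median population age."""
    regions = sorted(set(case_changes) & set(age_changes))
    if len(regions) < 3:
        raise DomainError(f"need >= 3 regions with both changes, got {len(regions)}")
    x = np.array([case_changes[r] for r in regions], dtype=float)
    y = np.array([age_changes[r] for r in regions], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in one of the change series")
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
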