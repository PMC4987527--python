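"""Study-size-weighted pooling of incidence and duration, and the
country-to-continent extrapolation behind the global case estimate.

Where several incidence studies exist for one continent (e.g. China, Japan,
Taiwan and Iran for Asia), their harmonized rates and median durations are
combined as a convex mixture weighted by each study's catchment population.
Continents with a single source study (United States -> North America,
Uruguay -> South America, Libya -> Africa, New Zealand -> Oceania, the
EU28 pooled analysis -> Europe) simply reuse that study's schedule.  The
assignment is a plain CSV so alternative mappings are one edit away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .agebands import STANDARD_GRID, AgeBand
from .errors import ConfigError, FormatError, ValidationError
from .incidence import SEXES, DurationModel
from .population import HarmonizedRates, PopulationPyramid
from .projection import CaseProjection, project_cases


@dataclass(frozen=True)
class PooledSchedule:
    """Convex, study-size-weighted combination of regional schedules.

    ``components`` records (region, normalized weight); weights are positive
    and sum to one, and every pooled band rate lies between the component
    minimum and maximum for that band.
    """

    continent_id: str
    sex: str
    rates: Mapping[AgeBand, float]
    components: tuple[tuple[str, float], ...]
    pooled_duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", dict(self.rates))
        wsum = sum(w for _, w in self.components)
        if any(w <= 0 for _, w in self.components) or abs(wsum - 1.0) > 1e-12:
            raise ValidationError(
                f"pooling weights for {self.continent_id}/{self.sex} must be positive "
                f"and sum to 1 (got sum {wsum!r})"
            )
        if not (self.pooled_duration > 0 and math.isfinite(self.pooled_duration)):
            raise ValidationError(f"pooled duration must be positive ({self.continent_id})")

    def as_harmonized(self) -> HarmonizedRates:
        """View the pooled schedule as a continent-level harmonized schedule."""
        return HarmonizedRates(region_id=self.continent_id, sex=self.sex, rates=self.rates)


def pool(
    schedules: Sequence[HarmonizedRates],
    durations: Mapping[str, DurationModel],
    *,
    continent_id: str,
) -> PooledSchedule:
    """Pool one sex's harmonized schedules with study-population weights.

    weight_i = study_population_i / sum(study_population); pooled band rate
    and pooled duration are the corresponding convex combinations.
    """
    if not schedules:
        raise ConfigError(f"no schedules to pool for {continent_id}")
    sexes = {s.sex for s in schedules}
    if len(sexes) != 1:
        raise ConfigError(f"pool() mixes sexes {sorted(sexes)}; pool one sex at a time")
    for s in schedules:
        if s.study_population is None or s.study_population <= 0:
            raise ConfigError(f"schedule {s.region_id}/{s.sex} lacks a study population weight")
        if s.region_id not in durations:
            raise ConfigError(f"no duration available for pooled region {s.region_id}")
    total_w = sum(s.study_population for s in schedules)  # type: ignore[misc]
    components = tuple((s.region_id, s.study_population / total_w) for s in schedules)  # type: ignore[operator]
    weights = dict(components)
    rates = {
        band: sum(weights[s.region_id] * s.rates[band] for s in schedules)
        for band in STANDARD_GRID
    }
    duration = sum(
        weights[s.region_id] * durations[s.region_id].median_duration for s in schedules
    )
    return PooledSchedule(
        continent_id=continent_id,
        sex=sexes.pop(),
        rates=rates,
        components=components,
        pooled_duration=duration,
    )


def extrapolate_global(
    sources: Mapping[str, Mapping[str, HarmonizedRates]],
    continent_pyramids: Sequence[PopulationPyramid],
    durations: Mapping[str, float],
) -> tuple[dict[tuple[str, int], CaseProjection], dict[int, float]]:
    """Project every continent-year pyramid with its assigned rate source.

    ``sources`` maps continent -> sex -> harmonized rates already relabelled
    to the continent (use :meth:`PooledSchedule.as_harmonized` or
    :func:`assign_source`); ``durations`` maps continent -> median duration
    in years.  Returns ((continent, year) -> projection, year -> world
    total).
    """
    projections: dict[tuple[str, int], CaseProjection] = {}
    world: dict[int, float] = {}
    for pyramid in continent_pyramids:
        cont = pyramid.region_id
        if cont not in sources:
            raise ConfigError(f"continent {cont!r} has a pyramid but no incidence source")
        if cont not in durations:
            raise ConfigError(f"continent {cont!r} has no assigned duration")
        dur = DurationModel(region_id=cont, median_duration=durations[cont])
        proj = project_cases(sources[cont], pyramid, dur)
        projections[(cont, pyramid.year)] = proj
        world[pyramid.year] = world.get(pyramid.year, 0.0) + proj.total
    return projections, dict(sorted(world.items()))


def assign_source(rates: Mapping[str, HarmonizedRates], continent_id: str) -> dict[str, HarmonizedRates]:
    """Relabel a single region's per-sex schedules to represent a continent."""
    return {
        sex: HarmonizedRates(region_id=continent_id, sex=sex, rates=hr.rates)
        for sex, hr in rates.items()
    }


def read_assignment_csv(path) -> dict[str, str]:
    """Read ``continent,source_region`` rows (single-study continents)."""
    df = pd.read_csv(path)
    for col in ("continent", "source_region"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column(s) {col}")
    return {str(r["continent"]): str(r["source_region"]) for _, r in df.iterrows()}


def read_membership_csv(path) -> dict[str, list[str]]:
    """Read ``continent,member_region`` rows (pooled continents)."""
    df = pd.read_csv(path)
    for col in ("continent", "member_region"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column(s) {col}")
    out: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["continent"]), []).append(str(r["member_region"]))
    return out
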