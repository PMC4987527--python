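"""Synthetic worlds with the statistical structure the projection assumes,
plus an illness-death microsimulation oracle.

The generator emulates what the real inputs look like: ageing population
pyramids (a 2015-style pyramid and a 2040-style pyramid with mass shifted
into the 60+ bands), incidence schedules on coarse study bands peaking at
ages 60-79 with a male excess, region-specific median durations in the 2-4
year range typical of ALS survival, and study catchment sizes for pooling
weights.  Alongside the data it returns closed-form expected case counts
computed by direct band-wise arithmetic — independent of the projection
module — so pipeline recovery can be tested exactly.

The microsimulation is the independent stochastic check of the stationary
prevalence approximation: onsets arise as a Poisson process at each band's
rate over the band's person-time, each case persists for its disease
duration, and prevalent cases are counted at a census instant.  Under
stationarity its mean matches incidence x duration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .agebands import STANDARD_GRID, AgeBand
from .errors import DomainError, ValidationError
from .incidence import (
    DurationModel,
    IncidenceSchedule,
    write_durations,
    write_incidence_table,
)
from .population import HarmonizedRates, PopulationPyramid, write_idb_csv
from .projection import CONTINENTS, RegionHierarchy

# Ten-year study bands from age 20 with an open 80+ tail; all are unions of
# standard 5-year grid bands, so harmonization is exact containment.
_STUDY_BANDS: tuple[AgeBand, ...] = tuple(
    [AgeBand(lo, lo + 9) for lo in range(20, 80, 10)] + [AgeBand(80)]
)


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Parameters of a generated world; a single seed fixes every draw.

    ageing_index scales the exponential age profile's mean between the two
    epochs (0 = stationary pyramid); peak_rate is the incidence plateau per
    100,000 person-years over peak_band, with multiplicative decay per
    decade younger (young_decay) and a reduced open-tail rate (old_decay),
    reflecting the observed 60-79 peak in ALS incidence.
    """

    n_regions: int = 3
    seed: int = 0
    total_population: float = 5_000_000.0
    population_growth: float = 1.15
    ageing_index: float = 0.2
    peak_rate: float = 6.0
    peak_band: tuple[int, int] = (60, 79)
    young_decay: float = 0.45
    old_decay: float = 0.6
    male_excess: float = 1.3
    duration_range: tuple[float, float] = (2.0, 4.0)
    catchment_range: tuple[float, float] = (5e5, 5e6)
    years: tuple[int, int] = (2015, 2040)

    def __post_init__(self) -> None:
        for name in ("total_population", "population_growth", "peak_rate", "male_excess"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_regions < 1:
            raise ValidationError("need at least one region")
        if self.ageing_index < 0:
            raise ValidationError("ageing_index must be >= 0")
        if not (0 < self.young_decay <= 1 and 0 < self.old_decay <= 1):
            raise ValidationError("decay factors must lie in (0, 1]")
        if not 0 < self.duration_range[0] <= self.duration_range[1]:
            raise ValidationError("duration_range must be positive and ordered")


@dataclass(frozen=True)
class SyntheticWorld:
    """A generated world plus its embedded closed-form truth."""

    spec: SyntheticWorldSpec
    pyramids: tuple[PopulationPyramid, ...]
    schedules: tuple[IncidenceSchedule, ...]
    durations: tuple[DurationModel, ...]
    hierarchy: RegionHierarchy
    #: (region, year) -> {"male": cases, "female": cases, "total": cases},
    #: computed by direct arithmetic independent of the projection module.
    truth: dict[tuple[str, int], dict[str, float]]

    def persist(self, out_dir) -> dict[str, Path]:
        """Write the world in the package's own CSV dialects (plus truth as
        JSON), so generated fixtures double as format tests."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "incidence": out / "incidence.csv",
            "durations": out / "durations.csv",
            "population": out / "population.csv",
            "hierarchy": out / "hierarchy.csv",
            "truth": out / "truth.json",
        }
        write_incidence_table(list(self.schedules), paths["incidence"])
        write_durations(list(self.durations), paths["durations"])
        write_idb_csv(list(self.pyramids), paths["population"])
        with open(paths["hierarchy"], "w") as fh:
            fh.write("region,continent,development\n")
            for region in sorted(self.hierarchy.continent_of):
                fh.write(
                    f"{region},{self.hierarchy.continent_of[region]},"
                    f"{self.hierarchy.development_of[region]}\n"
                )
        serial = {
            f"{region}|{year}": cases for (region, year), cases in sorted(self.truth.items())
        }
        paths["truth"].write_text(json.dumps(serial, indent=1, sort_keys=True))
        return paths


def _age_profile(scale: float) -> np.ndarray:
    """Discrete exponential age density over single years 0..104."""
    ages = np.arange(105, dtype=float)
    w = np.exp(-ages / scale)
    return w / w.sum()


def _pyramid_counts(total: float, scale: float, male_share: float) -> dict[tuple[str, AgeBand], float]:
    profile = _age_profile(scale)
    counts: dict[tuple[str, AgeBand], float] = {}
    for band in STANDARD_GRID:
        hi = 104 if band.upper is None else band.upper
        band_total = total * float(profile[band.lower : hi + 1].sum())
        counts[("male", band)] = band_total * male_share
        counts[("female", band)] = band_total * (1.0 - male_share)
    return counts


def _study_rates(spec: SyntheticWorldSpec, region_factor: float, sex_factor: float) -> dict[AgeBand, float]:
    peak_lo, peak_hi = spec.peak_band
    rates: dict[AgeBand, float] = {}
    for band in _STUDY_BANDS:
        base = spec.peak_rate * region_factor * sex_factor
        if band.open_ended:
            rates[band] = base * spec.old_decay
        elif band.lower >= peak_lo and (band.upper or 0) <= peak_hi:
            rates[band] = base
        else:
            decades_below = max(0, (peak_lo - band.lower) // 10)
            rates[band] = base * spec.young_decay**decades_below
    return rates


def generate_world(spec: SyntheticWorldSpec) -> SyntheticWorld:
    """Generate pyramids for two epochs, schedules, durations, a hierarchy,
    and the closed-form expected case counts, deterministically under the
    spec's seed."""
    rng = np.random.default_rng(spec.seed)
    year0, year1 = spec.years

    pyramids: list[PopulationPyramid] = []
    schedules: list[IncidenceSchedule] = []
    durations: list[DurationModel] = []
    continent_of: dict[str, str] = {}
    development_of: dict[str, str] = {}
    truth: dict[tuple[str, int], dict[str, float]] = {}

    for i in range(spec.n_regions):
        region = f"R{i:02d}"
        scale0 = float(rng.uniform(30.0, 40.0))
        scale1 = scale0 * (1.0 + spec.ageing_index)
        male_share = float(rng.uniform(0.48, 0.52))
        total0 = spec.total_population * float(rng.uniform(0.5, 1.5))
        total1 = total0 * spec.population_growth
        pyr0 = PopulationPyramid(region, year0, _pyramid_counts(total0, scale0, male_share))
        pyr1 = PopulationPyramid(region, year1, _pyramid_counts(total1, scale1, male_share))
        pyramids += [pyr0, pyr1]

        region_factor = float(rng.lognormal(mean=0.0, sigma=0.15))
        catchment = float(rng.uniform(*spec.catchment_range))
        sex_rates = {
            "male": _study_rates(spec, region_factor, spec.male_excess),
            "female": _study_rates(spec, region_factor, 1.0),
        }
        for sex in ("male", "female"):
            schedules.append(
                IncidenceSchedule(
                    region_id=region,
                    sex=sex,
                    entries=tuple((b, sex_rates[sex][b]) for b in _STUDY_BANDS),
                    study_population=catchment,
                    case_definition="ALS",
                )
            )
        duration = float(rng.uniform(*spec.duration_range))
        durations.append(DurationModel(region_id=region, median_duration=duration))
        continent_of[region] = CONTINENTS[i % len(CONTINENTS)]
        development_of[region] = "developed" if i % 2 == 0 else "developing"

        # Closed-form truth by direct arithmetic: every study band is a union
        # of grid bands, so expected cases are rate/1e5 x covered population
        # x duration, summed over study bands.  Deliberately not project_cases.
        for pyr in (pyr0, pyr1):
            per_sex: dict[str, float] = {}
            for sex in ("male", "female"):
                cases = 0.0
                for sb in _STUDY_BANDS:
                    covered = 0.0
                    for gb in STANDARD_GRID:
                        inside = (
                            gb.lower >= sb.lower
                            if sb.open_ended
                            else (gb.lower >= sb.lower and gb.upper is not None and gb.upper <= sb.upper)
                        )
                        if inside:
                            covered += pyr.counts[(sex, gb)]
                    cases += sex_rates[sex][sb] / 100_000.0 * covered * duration
                per_sex[sex] = cases
            truth[(region, pyr.year)] = {**per_sex, "total": per_sex["male"] + per_sex["female"]}

    hierarchy = RegionHierarchy(continent_of=continent_of, development_of=development_of)
    return SyntheticWorld(
        spec=spec,
        pyramids=tuple(pyramids),
        schedules=tuple(schedules),
        durations=tuple(durations),
        hierarchy=hierarchy,
        truth=truth,
    )


def microsim_prevalence(
    schedule: HarmonizedRates,
    pyramid: PopulationPyramid,
    duration: DurationModel,
    n_reps: int,
    seed: int,
    *,
    distribution: str = "fixed",
) -> tuple[float, float]:
    """Point prevalence of an illness-death process, mean +/- SE over reps.

    Per standard band, onsets arise as a Poisson process with intensity
    rate/100,000 x band population per year in a stationary regime; each
    case persists for its disease duration (default fixed at the median —
    the projection multiplies by the median, not the mean — or
    exponential with that median); cases alive at the census instant are
    counted.  Returns (mean prevalent count, Monte Carlo standard error).
    """
    if n_reps < 1:
        raise DomainError(f"n_reps must be >= 1, got {n_reps}")
    if distribution not in ("fixed", "exponential"):
        raise DomainError(f"distribution must be 'fixed' or 'exponential', got {distribution!r}")
    rng = np.random.default_rng(seed)
    pop = pyramid.band_counts(schedule.sex)
    lam = np.array([schedule.rates[b] / 100_000.0 * pop[b] for b in STANDARD_GRID])
    med = duration.median_duration
    if distribution == "fixed":
        window = med  # onsets older than the fixed duration are already dead
    else:
        window = med / math.log(2.0) * 40.0  # survival beyond this is ~e^-40

    totals = np.empty(n_reps)
    for rep in range(n_reps):
        prevalent = 0
        n_onsets = rng.poisson(lam * window)
        k = int(n_onsets.sum())
        if k > 0:
            onset_ages = rng.uniform(0.0, window, size=k)  # time before census
            if distribution == "fixed":
                survived = np.full(k, True)  # onset within the last `med` years
            else:
                scale = med / math.log(2.0)
                survived = rng.exponential(scale, size=k) > onset_ages
            prevalent = int(survived.sum())
        totals[rep] = prevalent
    mean = float(totals.mean())
    se = float(totals.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0
    return mean, se
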