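"""Extrapolate study-country incidence to continents and a world total.

One continent takes a single study's rates directly; another pools two
studies weighted by catchment size (weights 0.25/0.75 here).  Each
continent pyramid is then projected and the world total is the sum.
"""

from alsproj.agebands import AgeBand, STANDARD_GRID
from alsproj.incidence import DurationModel, IncidenceSchedule
from alsproj.pooling import assign_source, extrapolate_global, pool
from alsproj.population import PopulationPyramid, harmonize


def flat_schedule(region, sex, rate, catchment):
    return IncidenceSchedule(
        region_id=region, sex=sex,
        entries=((AgeBand(20), rate),),  # flat above age 20
        study_population=catchment,
    )


def uniform_pyramid(region, per_band):
    counts = {(s, b): per_band for s in ("male", "female") for b in STANDARD_GRID}
    return PopulationPyramid(region_id=region, year=2015, counts=counts)


rates = {
    region: {
        sex: harmonize(flat_schedule(region, sex, rate, catchment))
        for sex in ("male", "female")
    }
    for region, rate, catchment in (
        ("StudyA", 2.0, 1e6),   # sole study for continent Africa
        ("StudyB", 1.0, 1e6),   # pooled into Asia, weight 0.25
        ("StudyC", 3.0, 3e6),   # pooled into Asia, weight 0.75
    )
}
durations = {
    "StudyA": DurationModel("StudyA", 3.0),
    "StudyB": DurationModel("StudyB", 2.0),
    "StudyC": DurationModel("StudyC", 4.0),
}

asia_by_sex = {
    sex: pool([rates["StudyB"][sex], rates["StudyC"][sex]], durations, continent_id="Asia")
    for sex in ("male", "female")
}
for name, w in asia_by_sex["male"].components:
    print(f"Asia pooling weight for {name}: {w:.2f}")
print(f"Asia pooled duration: {asia_by_sex['male'].pooled_duration:.2f} years")

sources = {
    "Africa": assign_source(rates["StudyA"], "Africa"),
    "Asia": {sex: ps.as_harmonized() for sex, ps in asia_by_sex.items()},
}
continent_durations = {
    "Africa": durations["StudyA"].median_duration,
    "Asia": asia_by_sex["male"].pooled_duration,
}
pyramids = [uniform_pyramid("Africa", 10_000.0), uniform_pyramid("Asia", 20_000.0)]

projections, world = extrapolate_global(sources, pyramids, continent_durations)
for (continent, year), proj in sorted(projections.items()):
    print(f"{continent} {year}: {proj.total:,.1f} expected cases")
print(f"world total 2015: {world[2015]:,.1f}")

# The pooled Asia rate is the catchment-weighted mean 1.0*0.25 + 3.0*0.75 =
# 2.5 per 100,000 above age 20; the world total is the sum of continents.
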