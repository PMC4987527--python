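import pytest

from alsproj.agebands import STANDARD_GRID, AgeBand
from alsproj.incidence import DurationModel, IncidenceSchedule
from alsproj.population import PopulationPyramid
from alsproj.synthetic import SyntheticWorldSpec, generate_world


def make_pyramid(region="Toy", year=2015, band_counts=None, default=0.0,
                 sexes=("male", "female")):
    """Complete standard-grid pyramid with selected (sex, band) overrides."""
    counts = {(sex, band): default for sex in sexes for band in STANDARD_GRID}
    if band_counts:
        counts.update(band_counts)
    return PopulationPyramid(region_id=region, year=year, counts=counts)


def make_schedule(region="Toy", sex="male", entries=((AgeBand(60, 69), 8.0),),
                  study_population=1_000_000.0, **kw):
    return IncidenceSchedule(
        region_id=region, sex=sex, entries=tuple(entries),
        study_population=study_population, **kw,
    )


@pytest.fixture(scope="session")
def small_world():
    """Seeded three-region synthetic world shared across tests."""
    return generate_world(SyntheticWorldSpec(n_regions=3, seed=20150811))


@pytest.fixture
def toy_duration():
    return DurationModel(region_id="Toy", median_duration=3.0)
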