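"""Pyramid I/O, IDB fetch caching, and age-band harmonization."""

import io
import json

import pytest

from alsproj.agebands import STANDARD_GRID, AgeBand
from alsproj.errors import FormatError, RetrievalError, ValidationError
from alsproj.incidence import IncidenceSchedule
from alsproj.population import (
    PopulationPyramid,
    fetch_idb,
    harmonize,
    read_idb_csv,
    write_idb_csv,
)
from conftest import make_pyramid, make_schedule


def _full_csv(country="Toy", year=2015, value=1000.0):
    lines = ["country,year,sex,age_lo,age_hi,population"]
    for sex in ("male", "female"):
        for band in STANDARD_GRID:
            hi = "" if band.upper is None else band.upper
            lines.append(f"{country},{year},{sex},{band.lower},{hi},{value}")
    return "\n".join(lines) + "\n"


class TestIdbCsv:
    def test_complete_file_yields_one_pyramid(self):
        (pyr,) = read_idb_csv(io.StringIO(_full_csv()))
        assert pyr.region_id == "Toy" and pyr.year == 2015
        assert pyr.total() == pytest.approx(42 * 1000.0)

    def test_missing_band_names_the_gap(self):
        text = "\n".join(
            line for line in _full_csv().splitlines() if not line.startswith("Toy,2015,male,50,54")
        )
        with pytest.raises(ValidationError, match="50-54"):
            read_idb_csv(io.StringIO(text))

    def test_group_label_dialect(self):
        lines = ["country,year,sex,GROUP,population"]
        for sex in ("male", "female"):
            for band in STANDARD_GRID:
                lines.append(f"Toy,2015,{sex},{band.label},10")
        (pyr,) = read_idb_csv(io.StringIO("\n".join(lines)))
        assert pyr.counts[("female", AgeBand(100))] == 10

    def test_non_standard_band_rejected(self):
        text = _full_csv().replace("Toy,2015,male,50,54", "Toy,2015,male,50,57")
        with pytest.raises(FormatError, match="non-standard"):
            read_idb_csv(io.StringIO(text))

    def test_negative_population_rejected(self):
        text = _full_csv().replace("male,20,24,1000.0", "male,20,24,-5")
        with pytest.raises(ValidationError, match="negative"):
            read_idb_csv(io.StringIO(text))

    def test_round_trip(self):
        pyr = make_pyramid(band_counts={("male", AgeBand(60, 64)): 123.456}, default=7.0)
        buf = io.StringIO()
        write_idb_csv([pyr], buf)
        buf.seek(0)
        (back,) = read_idb_csv(buf)
        assert back == pyr


class TestFetchIdb:
    def test_replayed_payload_matches_direct_parse_and_cache_hits(self, tmp_path):
        payload = _full_csv()
        calls = []

        def downloader(url):
            calls.append(url)
            return payload

        got = fetch_idb(["Toy"], [2015], tmp_path, downloader=downloader, vintage="v-test")
        assert got == read_idb_csv(io.StringIO(payload))
        assert len(calls) == 1

        def exploding(url):  # warm cache: the network must not be touched
            raise AssertionError("network accessed despite warm cache")

        again = fetch_idb(["Toy"], [2015], tmp_path, downloader=exploding)
        assert again == got
        record = json.loads(next(tmp_path.glob("idb_*.json")).read_text())
        assert record["vintage"] == "v-test" and "source_url" in record

    def test_incomplete_payload_never_yields_partial_pyramids(self, tmp_path):
        with pytest.raises(RetrievalError, match="Toy/2040"):
            fetch_idb(["Toy"], [2015, 2040], tmp_path, downloader=lambda url: _full_csv())
        # the bad payload was cached but must still fail on replay
        with pytest.raises(RetrievalError):
            fetch_idb(["Toy"], [2015, 2040], tmp_path, downloader=lambda url: _full_csv())


class TestHarmonize:
    def test_full_containment_copies_rate(self):
        hr = harmonize(make_schedule(entries=[(AgeBand(45, 54), 3.0)]))
        assert hr.rates[AgeBand(45, 49)] == 3.0
        assert hr.rates[AgeBand(50, 54)] == 3.0
        assert hr.rates[AgeBand(55, 59)] == 0.0

    def test_partial_overlap_scales_by_year_fraction(self):
        # years 18 and 19 of the 15-19 band are covered: 2 of 5 years
        hr = harmonize(make_schedule(entries=[(AgeBand(18, 24), 5.0)]))
        assert hr.rates[AgeBand(15, 19)] == pytest.approx(5.0 * 2 / 5)
        assert hr.rates[AgeBand(20, 24)] == 5.0

    def test_open_band_propagates_to_all_older_bands(self):
        hr = harmonize(make_schedule(entries=[(AgeBand(75), 4.0)]))
        for band in STANDARD_GRID:
            expected = 4.0 if band.lower >= 75 else 0.0
            assert hr.rates[band] == expected
        assert hr.rates[AgeBand(100)] == 4.0

    def test_idempotent_on_grid_aligned_schedule(self):
        entries = [(b, float(i)) for i, b in enumerate(STANDARD_GRID)]
        hr = harmonize(make_schedule(entries=entries))
        assert hr.rates == {b: float(i) for i, b in enumerate(STANDARD_GRID)}

    def test_rates_bounded_by_study_maximum(self):
        entries = [(AgeBand(22, 33), 7.0), (AgeBand(40, 61), 2.0), (AgeBand(70), 5.5)]
        hr = harmonize(make_schedule(entries=entries))
        assert max(hr.rates.values()) <= 7.0

    def test_mass_conservation_on_aligned_study_bands(self):
        # study bands that are unions of grid bands: expected cases must agree
        entries = [(AgeBand(40, 49), 3.0), (AgeBand(50, 69), 6.0), (AgeBand(70), 4.0)]
        sched = make_schedule(entries=entries)
        hr = harmonize(sched)
        pyr = make_pyramid(default=1000.0)
        pop = pyr.band_counts("male")
        harmonized_mass = sum(hr.rates[b] * pop[b] for b in STANDARD_GRID)
        study_mass = 0.0
        for sb, rate in entries:
            covered = sum(
                pop[gb]
                for gb in STANDARD_GRID
                if gb.lower >= sb.lower and (sb.upper is None or (gb.upper or 104) <= sb.upper)
            )
            study_mass += rate * covered
        assert harmonized_mass == pytest.approx(study_mass, rel=1e-12)

    def test_extend_oldest_carries_terminal_rate(self):
        entries = [(AgeBand(60, 79), 6.0)]
        default = harmonize(make_schedule(entries=entries))
        extended = harmonize(make_schedule(entries=entries), extend_oldest=True)
        assert default.rates[AgeBand(85, 89)] == 0.0
        assert extended.rates[AgeBand(85, 89)] == 6.0
        assert extended.rates[AgeBand(100)] == 6.0

    def test_full_overlap_mode_carries_whole_rate(self):
        hr = harmonize(make_schedule(entries=[(AgeBand(18, 24), 5.0)]), overlap="full")
        assert hr.rates[AgeBand(15, 19)] == 5.0
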