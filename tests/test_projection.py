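"""The incidence x population x duration product and its analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alsproj.agebands import STANDARD_GRID, AgeBand
from alsproj.errors import ConfigError, DomainError
from alsproj.incidence import DurationModel
from alsproj.population import HarmonizedRates
from alsproj.projection import (
    RegionHierarchy,
    ageing_correlation,
    aggregate,
    median_population_age,
    percent_change,
    project_cases,
    round_half_away,
)
from conftest import make_pyramid


def rates_from(band_rates, region="Toy", sex="male"):
    rates = {b: 0.0 for b in STANDARD_GRID}
    rates.update(band_rates)
    return HarmonizedRates(region_id=region, sex=sex, rates=rates)


class TestProjectCases:
    def test_zero_rates_give_zero_cases(self, toy_duration):
        pyr = make_pyramid(default=50_000.0)
        proj = project_cases({"male": rates_from({})}, pyr, toy_duration)
        assert proj.total == 0.0

    def test_single_stratum_product(self, toy_duration):
        # 2 per 100,000 x 100,000 persons x 3 years = 6 expected cases
        pyr = make_pyramid(band_counts={("male", AgeBand(60, 64)): 100_000.0})
        proj = project_cases(
            {"male": rates_from({AgeBand(60, 64): 2.0})}, pyr, toy_duration
        )
        assert proj.total == pytest.approx(6.0)
        assert proj.cases_by_band[("male", AgeBand(60, 64))] == pytest.approx(6.0)

    def test_two_band_hand_sum(self):
        # (4/1e5 * 2.5e5 + 10/1e5 * 5e4) * 2.5 = (10 + 5) * 2.5 = 37.5
        pyr = make_pyramid(
            band_counts={
                ("male", AgeBand(60, 64)): 250_000.0,
                ("male", AgeBand(65, 69)): 50_000.0,
            }
        )
        rates = rates_from({AgeBand(60, 64): 4.0, AgeBand(65, 69): 10.0})
        proj = project_cases(
            {"male": rates}, pyr, DurationModel("Toy", 2.5)
        )
        assert proj.total == pytest.approx(37.5)

    def test_sex_sums_equal_band_sums(self, toy_duration):
        pyr = make_pyramid(default=10_000.0)
        rates = {
            "male": rates_from({AgeBand(60, 64): 5.0, AgeBand(80, 84): 3.0}),
            "female": rates_from({AgeBand(60, 64): 4.0}, sex="female"),
        }
        proj = project_cases(rates, pyr, toy_duration)
        for sex, total in proj.cases_by_sex.items():
            band_sum = sum(v for (s, _), v in proj.cases_by_band.items() if s == sex)
            assert total == pytest.approx(band_sum, rel=1e-9)

    def test_region_mismatch_is_config_error(self, toy_duration):
        pyr = make_pyramid(region="Other")
        with pytest.raises(ConfigError):
            project_cases({"male": rates_from({})}, pyr, toy_duration)

    @settings(max_examples=40, derandomize=True)
    @given(
        rate=st.floats(0.1, 20),
        pop=st.floats(1e3, 1e7),
        dur=st.floats(0.5, 10),
        scale=st.floats(0.1, 8),
    )
    def test_linearity_in_duration_and_population(self, rate, pop, dur, scale):
        pyr = make_pyramid(band_counts={("male", AgeBand(70, 74)): pop})
        scaled_pyr = make_pyramid(band_counts={("male", AgeBand(70, 74)): pop * scale})
        rates = {"male": rates_from({AgeBand(70, 74): rate})}
        base = project_cases(rates, pyr, DurationModel("Toy", dur)).total
        assert project_cases(rates, pyr, DurationModel("Toy", 2 * dur)).total == pytest.approx(
            2 * base, rel=1e-12
        )
        assert project_cases(rates, scaled_pyr, DurationModel("Toy", dur)).total == pytest.approx(
            scale * base, rel=1e-12
        )

    def test_monotonicity_in_rates_and_population(self, toy_duration):
        pyr = make_pyramid(default=10_000.0)
        base = project_cases(
            {"male": rates_from({AgeBand(60, 64): 5.0})}, pyr, toy_duration
        ).total
        bumped_rate = project_cases(
            {"male": rates_from({AgeBand(60, 64): 5.0, AgeBand(65, 69): 1.0})},
            pyr,
            toy_duration,
        ).total
        bigger_pop = make_pyramid(default=10_000.0, band_counts={("male", AgeBand(60, 64)): 20_000.0})
        bumped_pop = project_cases(
            {"male": rates_from({AgeBand(60, 64): 5.0})}, bigger_pop, toy_duration
        ).total
        assert bumped_rate >= base and bumped_pop >= base


class TestPercentChange:
    def test_published_global_totals_round_to_69(self):
        pc = percent_change(222_801, 376_674)
        assert pc == pytest.approx(69.06, abs=0.01)
        assert round_half_away(pc) == 69

    def test_identity_and_forced_arithmetic(self):
        assert percent_change(42.0, 42.0) == 0.0
        assert percent_change(100.0, 250.0) == 150.0

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 10.0)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(2.5) == 3


class TestAggregate:
    @staticmethod
    def _projection(region, year, total):
        cases = {(s, b): 0.0 for s in ("male", "female") for b in STANDARD_GRID}
        cases[("male", STANDARD_GRID[0])] = total
        from alsproj.projection import CaseProjection

        return CaseProjection(region_id=region, year=year, cases_by_band=cases)

    def test_single_region_share_is_one(self):
        hier = RegionHierarchy({"A": "Asia"}, {"A": "developing"})
        agg = aggregate([self._projection("A", 2015, 10.0)], hier, by="development")
        assert agg["developing"][2015].share == pytest.approx(1.0)

    def test_partition_conserves_grand_total(self):
        rng = np.random.default_rng(5)
        regions = [f"r{i}" for i in range(8)]
        hier = RegionHierarchy(
            {r: "Europe" for r in regions},
            {r: ("developed" if rng.random() < 0.5 else "developing") for r in regions},
        )
        projs = [self._projection(r, 2015, float(rng.uniform(1, 100))) for r in regions]
        agg = aggregate(projs, hier, by="development")
        grand = sum(p.total for p in projs)
        assert sum(g[2015].cases for g in agg.values()) == pytest.approx(grand, rel=1e-12)
        assert sum(g[2015].share for g in agg.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unclassified_region_is_named(self):
        hier = RegionHierarchy({"A": "Asia"}, {"A": "developing"})
        with pytest.raises(ConfigError, match="B"):
            aggregate([self._projection("B", 2015, 1.0)], hier, by="continent")


class TestMedianPopulationAge:
    def test_all_mass_in_one_band(self):
        pyr = make_pyramid(band_counts={("male", AgeBand(40, 44)): 1000.0})
        med = median_population_age(pyr)
        assert 40 <= med < 45

    def test_two_band_toy_closed_form(self):
        # equal mass in 0-4 and 100+: the 50th percentile sits exactly at the
        # top of the 0-4 band, so interpolation yields its upper boundary
        pyr = make_pyramid(
            band_counts={("male", AgeBand(0, 4)): 500.0, ("male", AgeBand(100)): 500.0}
        )
        assert median_population_age(pyr) == pytest.approx(5.0)

    def test_symmetric_pyramid_median_at_centre_midpoint(self):
        pyr = make_pyramid(
            band_counts={
                ("male", AgeBand(45, 49)): 100.0,
                ("male", AgeBand(50, 54)): 100.0,
                ("male", AgeBand(55, 59)): 100.0,
            }
        )
        assert median_population_age(pyr) == pytest.approx(52.5)

    def test_empty_pyramid_rejected(self):
        with pytest.raises(DomainError):
            median_population_age(make_pyramid(default=0.0))


class TestAgeingCorrelation:
    def test_collinear_pairs(self):
        cases = {"a": 10.0, "b": 20.0, "c": 30.0}
        ages = {"a": 1.0, "b": 2.0, "c": 3.0}
        assert ageing_correlation(cases, ages) == pytest.approx(1.0)
        anti = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert ageing_correlation(cases, anti) == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(scale=0.5, size=20)
        cases = {f"r{i}": float(x[i]) for i in range(20)}
        ages = {f"r{i}": float(y[i]) for i in range(20)}
        expected = float(np.corrcoef(x, y)[0, 1])
        assert ageing_correlation(cases, ages) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            ageing_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        flat = {"a": 1.0, "b": 1.0, "c": 1.0}
        with pytest.raises(DomainError):
            ageing_correlation(flat, {"a": 1.0, "b": 2.0, "c": 3.0})
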