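"""Published reference numbers for the ten-region ALS projection.

These are the projected case counts by country, year and sex for the ten
regions with usable incidence studies, and the accompanying global totals,
as printed in the epidemiological literature.  They are inputs for the
aggregation-only analytics (developed/developing shares, group percent
changes) and for worked examples; the package never asserts them as its own
output.  The per-study incidence rates and durations behind them live in
supplementary material that is not printed, so they are not shipped here.
"""

from __future__ import annotations

from .projection import CaseProjection, RegionHierarchy

#: (region, year, sex) -> published projected case count.
TEN_REGION_CASES: dict[tuple[str, int, str], int] = {
    ("Libya", 2015, "male"): 198,
    ("Libya", 2015, "female"): 95,
    ("Libya", 2040, "male"): 433,
    ("Libya", 2040, "female"): 202,
    ("UnitedStates", 2015, "male"): 12_656,
    ("UnitedStates", 2015, "female"): 9_179,
    ("UnitedStates", 2040, "male"): 17_184,
    ("UnitedStates", 2040, "female"): 12_122,
    ("Uruguay", 2015, "male"): 146,
    ("Uruguay", 2015, "female"): 61,
    ("Uruguay", 2040, "male"): 193,
    ("Uruguay", 2040, "female"): 76,
    ("China", 2015, "male"): 12_261,
    ("China", 2015, "female"): 8_068,
    ("China", 2040, "male"): 17_281,
    ("China", 2040, "female"): 12_453,
    ("Iran", 2015, "male"): 774,
    ("Iran", 2015, "female"): 635,
    ("Iran", 2040, "male"): 1_699,
    ("Iran", 2040, "female"): 1_293,
    ("Japan", 2015, "male"): 3_241,
    ("Japan", 2015, "female"): 2_625,
    ("Japan", 2040, "male"): 3_558,
    ("Japan", 2040, "female"): 2_873,
    ("Taiwan", 2015, "male"): 345,
    ("Taiwan", 2015, "female"): 277,
    ("Taiwan", 2040, "male"): 432,
    ("Taiwan", 2040, "female"): 364,
    ("EU28", 2015, "male"): 15_960,
    ("EU28", 2015, "female"): 13_248,
    ("EU28", 2040, "male"): 19_320,
    ("EU28", 2040, "female"): 15_704,
    ("Serbia", 2015, "male"): 74,
    ("Serbia", 2015, "female"): 52,
    ("Serbia", 2040, "male"): 69,
    ("Serbia", 2040, "female"): 48,
    ("NewZealand", 2015, "male"): 154,
    ("NewZealand", 2015, "female"): 111,
    ("NewZealand", 2040, "male"): 226,
    ("NewZealand", 2040, "female"): 165,
}

#: Published sex totals per year (these include display rounding: the table
#: cells sum to one less in each column).
PUBLISHED_SEX_TOTALS: dict[tuple[int, str], int] = {
    (2015, "male"): 45_810,
    (2015, "female"): 34_352,
    (2040, "male"): 60_394,
    (2040, "female"): 45_299,
}

#: Published overall ten-region totals per year.
PUBLISHED_OVERALL_TOTALS: dict[int, int] = {2015: 80_162, 2040: 105_693}

#: Published global (all-continent) totals per year.
PUBLISHED_GLOBAL_TOTALS: dict[int, int] = {2015: 222_801, 2040: 376_674}

_CONTINENT = {
    "Libya": "Africa",
    "UnitedStates": "NorthAmerica",
    "Uruguay": "SouthAmerica",
    "China": "Asia",
    "Iran": "Asia",
    "Japan": "Asia",
    "Taiwan": "Asia",
    "EU28": "Europe",
    "Serbia": "Europe",
    "NewZealand": "Oceania",
}
_DEVELOPED = {"EU28", "Japan", "NewZealand", "UnitedStates"}


def ten_region_hierarchy() -> RegionHierarchy:
    """The fixed classification used in the ten-region analysis: developed =
    Europe (EU28), Japan, New Zealand, United States; developing = China,
    Iran, Libya, Serbia, Taiwan, Uruguay."""
    return RegionHierarchy(
        continent_of=dict(_CONTINENT),
        development_of={
            r: ("developed" if r in _DEVELOPED else "developing") for r in _CONTINENT
        },
    )


def ten_region_projections() -> list[CaseProjection]:
    """The published per-country case counts wrapped as projections, with all
    cases placed in a single band (the published table is not age-resolved)."""
    from .agebands import STANDARD_GRID

    regions = sorted({r for r, _, _ in TEN_REGION_CASES})
    years = sorted({y for _, y, _ in TEN_REGION_CASES})
    out = []
    carrier = STANDARD_GRID[0]
    for region in regions:
        for year in years:
            cases = {
                (sex, band): (
                    float(TEN_REGION_CASES[(region, year, sex)]) if band == carrier else 0.0
                )
                for sex in ("male", "female")
                for band in STANDARD_GRID
            }
            out.append(CaseProjection(region_id=region, year=year, cases_by_band=cases))
    return out
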