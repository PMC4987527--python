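"""Aggregate the published ten-region case table into trend headlines.

Feeds the published 2015/2040 projected ALS case counts for the ten study
regions through the package's aggregation and percent-change analytics:
the developed-country share of cases, each group's percent increase, and
the increase implied by the published global totals.
"""

from alsproj.datasets import (
    PUBLISHED_GLOBAL_TOTALS,
    ten_region_hierarchy,
    ten_region_projections,
)
from alsproj.projection import aggregate, percent_change, round_half_away

projections = ten_region_projections()
hierarchy = ten_region_hierarchy()

dev = aggregate(projections, hierarchy, by="development")
for year in (2015, 2040):
    share = 100.0 * dev["developed"][year].share
    print(f"developed share of cases, {year}: {share:.1f}% (reported: {round_half_away(share):.0f}%)")

for group in ("developing", "developed"):
    pc = percent_change(dev[group][2015].cases, dev[group][2040].cases)
    print(f"{group} increase 2015->2040: {pc:.1f}% (reported: {round_half_away(pc):.0f}%)")

total = aggregate(projections, hierarchy, by="all")["all"]
print(f"ten-region total increase: {percent_change(total[2015].cases, total[2040].cases):.1f}%")

g = percent_change(PUBLISHED_GLOBAL_TOTALS[2015], PUBLISHED_GLOBAL_TOTALS[2040])
print(f"global increase from published world totals: {g:.1f}%")

# The shares show the weight of ALS shifting toward developing countries:
# their case load grows twice as fast because their populations age fastest.
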