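"""Report tables and machine-readable summaries.

Two output layers: a human table with counts rounded half away from zero
and thousands separators, and machine CSV/JSON at full precision with
provenance (input digests, population-data vintage, software version,
config hash).  Display rounding never feeds back into computation — summing
rounded cells can miss the true total by a count or two, which is exactly
the artefact the unrounded layer avoids.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .projection import (
    CaseProjection,
    GroupTotal,
    RegionHierarchy,
    aggregate,
    percent_change,
    round_half_away,
)


def cases_frame(projections: Sequence[CaseProjection]) -> pd.DataFrame:
    """Long-format ``region,year,sex,cases`` table at full precision."""
    rows = [
        {"region": p.region_id, "year": p.year, "sex": sex, "cases": total}
        for p in projections
        for sex, total in sorted(p.cases_by_sex.items())
    ]
    return pd.DataFrame(rows, columns=["region", "year", "sex", "cases"])


def write_cases_csv(projections: Sequence[CaseProjection], path) -> None:
    cases_frame(projections).to_csv(path, index=False)


def render_case_table(projections: Sequence[CaseProjection]) -> str:
    """Human-readable country x year x sex table with sex and overall totals,
    rounded half away from zero with thousands separators."""
    df = cases_frame(projections)
    years = sorted(df["year"].unique())
    lines = []
    header = ["region"] + [f"{y} {s}" for y in years for s in ("male", "female")]
    lines.append("\t".join(header))
    piv = df.pivot_table(index="region", columns=["year", "sex"], values="cases", aggfunc="sum")
    for region in piv.index:
        cells = [region]
        for y in years:
            for s in ("male", "female"):
                cells.append(f"{int(round_half_away(piv.loc[region, (y, s)])):,}")
        lines.append("\t".join(cells))
    totals = ["Total by sex"]
    overall = ["Overall total"]
    for y in years:
        for s in ("male", "female"):
            totals.append(f"{int(round_half_away(piv[(y, s)].sum())):,}")
    for y in years:
        overall.append(f"{int(round_half_away(piv[y].to_numpy().sum())):,}")
        overall.append("")
    lines.append("\t".join(totals))
    lines.append("\t".join(overall))
    return "\n".join(lines)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True).encode()
    ).hexdigest()[:16]


def summarize(
    projections: Sequence[CaseProjection],
    hierarchy: RegionHierarchy | None = None,
    *,
    inputs: Mapping[str, str] | None = None,
    config: Mapping | None = None,
    vintage: str | None = None,
) -> dict:
    """Build the machine-readable summary: totals, shares, percent changes
    and provenance.  Percent changes are reported both unrounded and at the
    integer presentation used in report tables."""
    years = sorted({p.year for p in projections})
    totals = {y: sum(p.total for p in projections if p.year == y) for y in years}
    summary: dict = {
        "years": years,
        "totals": {str(y): totals[y] for y in years},
    }
    if len(years) >= 2:
        first, last = years[0], years[-1]
        pc = percent_change(totals[first], totals[last])
        summary["percent_change"] = {
            "from": first,
            "to": last,
            "value": pc,
            "rounded": int(round_half_away(pc)),
        }
    if hierarchy is not None:
        groups: dict = {}
        for by in ("development", "continent"):
            try:
                agg = aggregate(list(projections), hierarchy, by=by)
            except Exception:
                continue
            groups[by] = {
                g: {
                    str(y): {
                        "cases": gt.cases,
                        "share": gt.share,
                        "share_pct_rounded": int(round_half_away(100.0 * gt.share)),
                    }
                    for y, gt in per_year.items()
                }
                for g, per_year in agg.items()
            }
            if len(years) >= 2:
                for g, per_year in agg.items():
                    if years[0] in per_year and years[-1] in per_year:
                        pc = percent_change(per_year[years[0]].cases, per_year[years[-1]].cases)
                        groups[by][g]["percent_change"] = {
                            "value": pc,
                            "rounded": int(round_half_away(pc)),
                        }
        summary["groups"] = groups
    summary["provenance"] = {
        "software_version": __version__,
        "input_digests": dict(inputs or {}),
        "population_data_vintage": vintage or "unspecified",
        "config_hash": config_hash(config or {}),
    }
    return summary


def write_summary_json(summary: Mapping, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=1, sort_keys=True))
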