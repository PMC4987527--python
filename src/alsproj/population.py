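"""Population pyramids on the standard 5-year grid, and age-band harmonization.

The population side of the projection comes from US Census Bureau
International Data Base (IDB) style tables: counts by country, calendar
year, sex and 5-year age band (0-4 ... 95-99, 100+).  Incidence studies
rarely report rates on that exact grid, so :func:`harmonize` maps a study's
age bands onto it: a grid band fully inside one study band inherits that
band's rate; a partially covered grid band gets the study rate scaled by
the fraction of its whole years covered (uniform age distribution within
the band); grid bands no study band touches get rate 0.  An open-ended
study band (e.g. 75+) covers every older grid band including 100+.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .agebands import STANDARD_GRID, AgeBand
from .errors import FormatError, RetrievalError, ValidationError
from .incidence import SEXES, IncidenceSchedule

_IDB_COLUMNS_BOUNDS = ["country", "year", "sex", "age_lo", "age_hi", "population"]

#: Default IDB API endpoint (timeseries dataset, 5-year age groups).
IDB_BASE_URL = "https://api.census.gov/data/timeseries/idb/5year"


@dataclass(frozen=True)
class PopulationPyramid:
    """Population counts by sex and standard 5-year band for one region-year.

    Counts are non-negative reals: the IDB supplies integers, synthetic data
    may be real-valued.  The band set must be exactly the 21-band standard
    grid for every sex present.
    """

    region_id: str
    year: int
    counts: Mapping[tuple[str, AgeBand], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        sexes = sorted({s for s, _ in self.counts})
        if not sexes:
            raise ValidationError(f"empty pyramid for {self.region_id}/{self.year}")
        grid = set(STANDARD_GRID)
        for sex in sexes:
            if sex not in SEXES:
                raise ValidationError(f"unknown sex {sex!r} in pyramid {self.region_id}")
            bands = {b for s, b in self.counts if s == sex}
            missing = grid - bands
            extra = bands - grid
            if missing:
                names = ", ".join(b.label for b in sorted(missing))
                raise ValidationError(
                    f"pyramid {self.region_id}/{self.year}/{sex} missing band(s): {names}"
                )
            if extra:
                names = ", ".join(b.label for b in sorted(extra))
                raise ValidationError(
                    f"pyramid {self.region_id}/{self.year}/{sex} has non-standard band(s): {names}"
                )
        for (sex, band), n in self.counts.items():
            if not (n >= 0 and math.isfinite(n)):
                raise ValidationError(
                    f"negative or non-finite population in {self.region_id}/{self.year}"
                    f"/{sex}/{band.label}: {n}"
                )

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.counts}))

    def total(self, sex: str | None = None) -> float:
        return sum(n for (s, _), n in self.counts.items() if sex is None or s == sex)

    def band_counts(self, sex: str) -> dict[AgeBand, float]:
        return {b: n for (s, b), n in self.counts.items() if s == sex}


@dataclass(frozen=True)
class HarmonizedRates:
    """Effective incidence per 100,000 person-years on the standard grid.

    Produced by :func:`harmonize`; carries the source study's catchment size
    so pooling can weight by it later.
    """

    region_id: str
    sex: str
    rates: Mapping[AgeBand, float]
    study_population: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", dict(self.rates))
        if set(self.rates) != set(STANDARD_GRID):
            raise ValidationError(
                f"harmonized rates for {self.region_id}/{self.sex} must cover the "
                f"standard grid exactly"
            )
        for band, r in self.rates.items():
            if not (r >= 0 and math.isfinite(r)):
                raise ValidationError(
                    f"negative or non-finite rate {r} in {self.region_id}/{self.sex}"
                    f"/{band.label}"
                )


def read_idb_csv(path) -> list[PopulationPyramid]:
    """Parse an IDB-style CSV into one pyramid per (country, year).

    Accepts either ``age_lo``/``age_hi`` columns (``age_hi`` blank for the
    open 100+ band) or a single ``GROUP`` label column (``"15-19"``,
    ``"100+"``).  Incomplete pyramids are an error, never imputed.
    """
    df = pd.read_csv(path, dtype={"age_hi": "string"}, float_precision="round_trip")
    group_col = next((c for c in df.columns if c.lower() == "group"), None)
    base = ["country", "year", "sex", "population"]
    missing = [c for c in base if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if group_col is None and not {"age_lo", "age_hi"} <= set(df.columns):
        raise FormatError(f"{path}: need either age_lo/age_hi columns or a GROUP column")

    pyramids = []
    for (country, year), grp in df.groupby(["country", "year"], sort=True):
        counts: dict[tuple[str, AgeBand], float] = {}
        for _, row in grp.iterrows():
            if group_col is not None:
                band = AgeBand.from_label(row[group_col])
            else:
                hi = row["age_hi"]
                band = AgeBand.from_bounds(row["age_lo"], None if pd.isna(hi) else hi)
            if band not in STANDARD_GRID:
                raise FormatError(
                    f"{path}: non-standard age band {band.label} for {country}/{year}"
                )
            key = (str(row["sex"]), band)
            if key in counts:
                raise FormatError(
                    f"{path}: duplicate band {band.label} for {country}/{year}/{row['sex']}"
                )
            counts[key] = float(row["population"])
        pyramids.append(PopulationPyramid(region_id=str(country), year=int(year), counts=counts))
    return pyramids


def write_idb_csv(pyramids: Sequence[PopulationPyramid], path) -> None:
    """Write pyramids in the ``country,year,sex,age_lo,age_hi,population``
    dialect; :func:`read_idb_csv` inverts it."""
    rows = []
    for p in pyramids:
        for sex in p.sexes:
            for band in STANDARD_GRID:
                rows.append(
                    {
                        "country": p.region_id,
                        "year": p.year,
                        "sex": sex,
                        "age_lo": band.lower,
                        "age_hi": "" if band.upper is None else band.upper,
                        "population": p.counts[(sex, band)],
                    }
                )
    pd.DataFrame(rows, columns=_IDB_COLUMNS_BOUNDS).to_csv(path, index=False)


def _default_downloader(url: str) -> str:
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:  # pragma: no cover
            return resp.read().decode("utf-8")
    except Exception as exc:  # pragma: no cover - network paths untestable offline
        raise RetrievalError(f"could not retrieve {url}: {exc}") from exc


def fetch_idb(
    countries: Sequence[str],
    years: Sequence[int],
    cache_dir,
    *,
    downloader: Callable[[str], str] | None = None,
    base_url: str = IDB_BASE_URL,
    vintage: str | None = None,
) -> list[PopulationPyramid]:
    """Fetch population pyramids for the given countries and years.

    Payloads are cached as one JSON file per (country, years) request, with
    the retrieval timestamp, source URL and database vintage recorded; warm
    reruns are served from the cache without touching the network.  The
    payload format is the IDB-style CSV dialect of :func:`read_idb_csv`.
    ``downloader`` is injectable so recorded responses can be replayed.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    fetch = downloader or _default_downloader
    pyramids: list[PopulationPyramid] = []
    year_key = ",".join(str(y) for y in years)
    for country in countries:
        cache_file = cache_dir / f"idb_{country}_{hashlib.sha256(year_key.encode()).hexdigest()[:12]}.json"
        url = f"{base_url}?{urllib.parse.urlencode({'GENC': country, 'YR': year_key})}"
        if cache_file.exists():
            record = json.loads(cache_file.read_text())
        else:
            payload = fetch(url)
            record = {
                "country": country,
                "years": list(years),
                "source_url": url,
                "retrieved_at": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
                "vintage": vintage or "unknown",
                "payload_csv": payload,
            }
            cache_file.write_text(json.dumps(record, indent=1))
        import io

        got = read_idb_csv(io.StringIO(record["payload_csv"]))
        found = {(p.region_id, p.year) for p in got}
        wanted = {(country, int(y)) for y in years}
        if not wanted <= found:
            gaps = ", ".join(f"{c}/{y}" for c, y in sorted(wanted - found))
            raise RetrievalError(
                f"payload for {country} incomplete (missing {gaps}); "
                f"no partial pyramids are returned"
            )
        pyramids.extend(p for p in got if (p.region_id, p.year) in wanted)
    return pyramids


def cache_vintage(cache_dir) -> str | None:
    """Report the IDB vintage recorded in a cache directory (for provenance)."""
    vintages = set()
    for f in Path(cache_dir).glob("idb_*.json"):
        vintages.add(json.loads(f.read_text()).get("vintage", "unknown"))
    if not vintages:
        return None
    return "; ".join(sorted(vintages))


def harmonize(
    schedule: IncidenceSchedule,
    grid: Sequence[AgeBand] = STANDARD_GRID,
    *,
    overlap: str = "proportional",
    extend_oldest: bool = False,
) -> HarmonizedRates:
    """Map a study's incidence schedule onto the standard 5-year grid.

    For each grid band the effective rate is the study-band rate weighted by
    the fraction of the grid band's whole years each study band covers
    (``overlap="proportional"``, uniform-within-band assumption), or the
    covering study band's full rate (``overlap="full"``, a sensitivity
    option).  Grid bands below the youngest study band get 0 (juvenile ALS
    is not modelled); bands above a bounded oldest study band get 0 unless
    ``extend_oldest`` carries the terminal rate upward.  An open-ended study
    band covers all older grid bands outright.
    """
    if overlap not in ("proportional", "full"):
        raise ValidationError(f"overlap must be 'proportional' or 'full', got {overlap!r}")
    rates: dict[AgeBand, float] = {}
    entries = schedule.entries
    oldest_band, oldest_rate = entries[-1] if entries else (None, 0.0)
    for gb in grid:
        eff = 0.0
        for sb, rate in entries:
            if sb.open_ended:
                if gb.lower >= sb.lower:
                    years = gb.width  # fully covered, incl. 100+
                else:
                    years = sb.overlap_years(gb)
            else:
                years = sb.overlap_years(gb)
            if years <= 0:
                continue
            if overlap == "full":
                eff = max(eff, rate)
            else:
                eff += rate * min(years, gb.width) / gb.width
        if (
            extend_oldest
            and eff == 0.0
            and oldest_band is not None
            and not oldest_band.open_ended
            and oldest_band.upper is not None
            and gb.lower > oldest_band.upper
        ):
            eff = oldest_rate
        rates[gb] = eff
    return HarmonizedRates(
        region_id=schedule.region_id,
        sex=schedule.sex,
        rates=rates,
        study_population=schedule.study_population,
    )
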