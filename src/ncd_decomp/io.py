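"""Reading and writing: mortality tables, region maps, tidy result tables.

Input CSV schema (UTF-8, "." decimal)::

    country,sex,year,age_start,cause_code,deaths,person_years

with ``rate`` accepted in place of the two count columns.  Detailed
cause codes are aggregated to the 20 cause groups by summing deaths
(or rates) before any probability is formed, so group aggregation
conserves total deaths exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .causes import CauseMap
from .grids import AgeGrid
from .surface import SEXES, MortalitySurface

__all__ = [
    "REGIONS",
    "QUALITY_TIERS",
    "RegionMap",
    "read_surface",
    "write_surface",
    "read_region_map",
    "select_decomposition_countries",
    "write_results",
]

#: the eight reporting regions
REGIONS = (
    "high_income_western",
    "central_eastern_europe",
    "central_asia_middle_east_north_africa",
    "east_southeast_asia",
    "south_asia",
    "latin_america_caribbean",
    "sub_saharan_africa",
    "pacific_islands",
)

QUALITY_TIERS = ("high", "medium", "low", "very_low")


@dataclass(frozen=True)
class RegionMap:
    """Country -> region, death-registration quality tier, and population.

    ``frame`` columns: country, region, quality, pop_female, pop_male
    (reference-year population in persons).  Every country appears
    once; populations are positive.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"country", "region", "quality", "pop_female", "pop_male"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"region map lacks columns: {sorted(missing)}")
        if df["country"].duplicated().any():
            dup = df.loc[df["country"].duplicated(), "country"].tolist()
            raise ValueError(f"countries listed more than once: {dup}")
        bad_region = set(df["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown regions: {sorted(bad_region)}")
        bad_quality = set(df["quality"]) - set(QUALITY_TIERS)
        if bad_quality:
            raise ValueError(f"unknown quality tiers: {sorted(bad_quality)}")
        if (df[["pop_female", "pop_male"]] <= 0).any().any():
            raise ValueError("populations must be positive")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.frame["country"])

    def region_of(self, country: str) -> str:
        return self._lookup(country, "region")

    def quality_of(self, country: str) -> str:
        return self._lookup(country, "quality")

    def population(self, country: str, sex: str | None = None) -> float:
        if sex is None:
            return self._lookup(country, "pop_female") + self._lookup(country, "pop_male")
        return self._lookup(country, f"pop_{sex}")

    def _lookup(self, country: str, col: str):
        row = self.frame.loc[self.frame["country"] == country, col]
        if row.empty:
            raise KeyError(f"country {country!r} not in region map")
        return row.iloc[0]


def read_region_map(path: str | Path) -> RegionMap:
    return RegionMap(pd.read_csv(path))


# ---------------------------------------------------------------------
# mortality surfaces

def read_surface(path: str | Path, cause_map: CauseMap, grid: AgeGrid) -> MortalitySurface:
    """Read a long-format mortality CSV and aggregate to the 20 cause groups.

    Detailed codes are mapped through ``cause_map`` and summed (deaths
    and rates alike; person-years are an age-band exposure shared by
    all causes and must agree across the rows of a cell).  Unmapped
    codes, negative counts, and missing cells are hard errors.
    """
    df = pd.read_csv(path)
    required = {"country", "sex", "year", "age_start", "cause_code"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_counts = {"deaths", "person_years"} <= set(df.columns)
    if not has_counts and "rate" not in df.columns:
        raise ValueError(f"{path}: need 'deaths'+'person_years' or 'rate'")

    codes = df["cause_code"].astype(str)
    unmapped = sorted(set(codes) - set(cause_map.code_to_group))
    if unmapped:
        raise ValueError(f"unmapped cause codes: {unmapped}")
    df = df.assign(cause=codes.map(cause_map.code_to_group))

    if has_counts and (df["deaths"] < 0).any():
        n = int((df["deaths"] < 0).sum())
        raise ValueError(f"{n} rows with negative death counts")

    keys = ["country", "sex", "year", "age_start", "cause"]
    if has_counts:
        py = df.groupby(["country", "sex", "year", "age_start"])["person_years"]
        spread = (py.max() - py.min()).abs()
        if (spread > 1e-6 * py.max().clip(lower=1.0)).any():
            raise ValueError("person_years differs between causes within an age band")
        agg = df.groupby(keys, as_index=False).agg(
            deaths=("deaths", "sum"), person_years=("person_years", "first")
        )
        agg["rate"] = agg["deaths"] / agg["person_years"]
    else:
        agg = df.groupby(keys, as_index=False).agg(rate=("rate", "sum"))
    return MortalitySurface.from_frame(agg, grid, causes=list(cause_map.groups))


def write_surface(surface: MortalitySurface, path: str | Path) -> None:
    """Write a surface in the input CSV schema (cause groups as cause codes).

    Rates round-trip through :func:`read_surface` with an identity
    cause map to full precision.
    """
    df = surface.to_frame().rename(columns={"cause": "cause_code"})
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------
# country selection for the cause-decomposition subset

def select_decomposition_countries(
    region_map: RegionMap,
    quality_overrides: Iterable[str] = (),
    population_floor: float = 2_000_000,
    medium_top_k: int = 5,
    include_region_largest: bool = True,
) -> list[str]:
    """Countries eligible for cause-specific decomposition.

    A country is selected if it

    - has high-quality death registration and a total population above
      ``population_floor``; or
    - is listed in ``quality_overrides`` (countries whose estimates
      draw on richer data than their registration tier suggests); or
    - has medium-quality data and is among the ``medium_top_k``
      largest countries of its region by population; or
    - is the largest country of its region irrespective of quality
      (when ``include_region_largest``).

    All rule parameters are configuration, not hard-coded.
    """
    df = region_map.frame.copy()
    df["pop"] = df["pop_female"] + df["pop_male"]

    overrides = list(quality_overrides)
    absent = sorted(set(overrides) - set(df["country"]))
    if absent:
        raise ValueError(f"override countries not in region map: {absent}")

    selected = set(df.loc[(df["quality"] == "high") & (df["pop"] > population_floor), "country"])
    selected |= set(overrides)

    for _, grp in df.groupby("region"):
        ranked = grp.sort_values(["pop", "country"], ascending=[False, True])
        top = ranked.head(medium_top_k)
        selected |= set(top.loc[top["quality"] == "medium", "country"])
        if include_region_largest and len(ranked):
            selected.add(ranked.iloc[0]["country"])
    return sorted(selected)


# ---------------------------------------------------------------------
# result tables

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write tidy result CSVs plus a JSON run manifest; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    mpath = out / "manifest.json"
    payload = dict(manifest or {})
    payload.setdefault("tables", sorted(tables))
    payload.setdefault("versions", {"numpy": np.__version__, "pandas": pd.__version__})
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
    written.append(mpath)
    return written
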