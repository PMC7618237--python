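"""Period changes, decadal classification, and cross-country summaries.

Change over a period is the difference between the unconditional
probability of death in the final and first year of the period (no
linearity assumption), expressed in percentage points.  Comparing the
2010-19 change with the 2001-10 change classifies each country into
one of six improvement/deterioration categories (plus an
unchanged-pace tie).  Summaries cover region means, shares of
population in declining countries, within-region convergence, the
level-change correlation, and regional benchmark selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .io import RegionMap

__all__ = [
    "ChangeRecord",
    "Category",
    "DecadalClass",
    "change",
    "change_table",
    "classify_decadal",
    "classification_table",
    "region_summary",
    "population_coverage",
    "convergence_sd",
    "level_change_correlation",
    "select_benchmark",
]


@dataclass(frozen=True)
class ChangeRecord:
    """Endpoint change in the probability of death, in percentage points."""

    country: str
    sex: str
    year_first: int
    year_last: int
    delta: float  # 100 * (q_last - q_first)


class Category(str, Enum):
    LARGER_DECLINE = "larger_decline"
    REVERSAL_OF_INCREASE = "reversal_of_increase"
    SMALLER_INCREASE = "smaller_increase"
    SMALLER_DECLINE = "smaller_decline"
    REVERSAL_OF_DECLINE = "reversal_of_decline"
    LARGER_INCREASE = "larger_increase"
    UNCHANGED_PACE = "unchanged_pace"


_DIRECTION = {
    Category.LARGER_DECLINE: "improvement",
    Category.REVERSAL_OF_INCREASE: "improvement",
    Category.SMALLER_INCREASE: "improvement",
    Category.SMALLER_DECLINE: "deterioration",
    Category.REVERSAL_OF_DECLINE: "deterioration",
    Category.LARGER_INCREASE: "deterioration",
    Category.UNCHANGED_PACE: "neutral",
}


@dataclass(frozen=True)
class DecadalClass:
    category: Category
    direction: str  # improvement | deterioration | neutral


def _value(prob: pd.DataFrame, country: str, sex: str, year: int) -> float:
    row = prob[(prob["country"] == country) & (prob["sex"] == sex) & (prob["year"] == year)]
    if row.empty:
        raise KeyError(f"no probability for (country={country!r}, sex={sex!r}, year={year})")
    return float(row["value"].iloc[0])


def change(
    prob: pd.DataFrame, country: str, sex: str, year_first: int, year_last: int
) -> ChangeRecord:
    """Percentage-point change between the endpoint years for one country/sex."""
    q0 = _value(prob, country, sex, year_first)
    q1 = _value(prob, country, sex, year_last)
    return ChangeRecord(country, sex, int(year_first), int(year_last), 100.0 * (q1 - q0))


def change_table(prob: pd.DataFrame, year_first: int, year_last: int) -> pd.DataFrame:
    """Endpoint changes for every (country, sex): columns country, sex, delta."""
    wide = prob.pivot_table(index=["country", "sex"], columns="year", values="value")
    for y in (year_first, year_last):
        if y not in wide.columns:
            raise KeyError(f"year {y} absent from the probability series")
    if wide[[year_first, year_last]].isna().any().any():
        bad = wide.index[wide[[year_first, year_last]].isna().any(axis=1)].tolist()
        raise KeyError(f"missing endpoint values for {bad[:5]}")
    out = wide.reset_index()[["country", "sex"]]
    out["delta"] = 100.0 * (wide[year_last] - wide[year_first]).to_numpy()
    return out


# ---------------------------------------------------------------------
# decadal classification

def classify_decadal(delta1: float, delta2: float, atol: float = 1e-9) -> DecadalClass:
    """Classify a (2001-10, 2010-19) change pair into the decadal scheme.

    Improvements: a larger decline, a reversal of an increase, or a
    smaller increase.  Deteriorations: a smaller decline, a reversal of
    a decline, or a larger increase.  Equal paces (and the measure-zero
    boundaries with a zero first-period change) are resolved as
    documented: ``delta2 == delta1`` is unchanged pace; a flat first
    period followed by a decline (increase) counts as a larger decline
    (increase).  Equality is assessed at ``atol`` (percentage points)
    so that floating-point ties classify as ties.
    """
    d1, d2 = float(delta1), float(delta2)
    if not (np.isfinite(d1) and np.isfinite(d2)):
        raise ValueError("deltas must be finite")
    if abs(d2 - d1) <= atol:
        cat = Category.UNCHANGED_PACE
    elif abs(d1) <= atol:  # flat first period
        cat = Category.LARGER_DECLINE if d2 < 0 else Category.LARGER_INCREASE
    elif abs(d2) <= atol:  # flat second period
        cat = Category.SMALLER_DECLINE if d1 < 0 else Category.SMALLER_INCREASE
    elif d1 < 0:
        if d2 < d1:
            cat = Category.LARGER_DECLINE
        elif d2 < 0:
            cat = Category.SMALLER_DECLINE
        else:
            cat = Category.REVERSAL_OF_DECLINE
    else:  # d1 > 0
        if d2 > d1:
            cat = Category.LARGER_INCREASE
        elif d2 > 0:
            cat = Category.SMALLER_INCREASE
        else:
            cat = Category.REVERSAL_OF_INCREASE
    return DecadalClass(cat, _DIRECTION[cat])


def classification_table(changes1: pd.DataFrame, changes2: pd.DataFrame) -> pd.DataFrame:
    """Merge two change tables and classify each (country, sex).

    Columns: country, sex, delta_first, delta_second, category, direction.
    """
    merged = changes1.merge(changes2, on=["country", "sex"], suffixes=("_first", "_second"))
    cls = [
        classify_decadal(r.delta_first, r.delta_second)
        for r in merged.itertuples(index=False)
    ]
    merged["category"] = [c.category.value for c in cls]
    merged["direction"] = [c.direction for c in cls]
    return merged


# ---------------------------------------------------------------------
# cross-country summaries

def _with_region(changes: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    merged = changes.merge(region_map.frame, on="country", how="left")
    if merged["region"].isna().any():
        missing = merged.loc[merged["region"].isna(), "country"].unique().tolist()
        raise KeyError(f"countries without a region: {missing}")
    return merged


def region_summary(changes: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Per-region mean decline and counts of declining countries.

    The mean decline is the unweighted mean of ``-delta`` over *all*
    countries in the region (increases enter negatively); ``n_declining``
    counts countries with ``delta < 0``.
    """
    merged = _with_region(changes, region_map)
    rows = []
    for (region, sex), grp in merged.groupby(["region", "sex"]):
        if grp.empty:
            continue
        rows.append(
            {
                "region": region,
                "sex": sex,
                "mean_decline_pp": float(-grp["delta"].mean()),
                "n_declining": int((grp["delta"] < 0).sum()),
                "n_total": int(len(grp)),
                "share_declining": float((grp["delta"] < 0).mean()),
            }
        )
    empty = set(region_map.frame["region"].unique()) - {r["region"] for r in rows}
    if empty:
        warnings.warn(f"regions without change records omitted: {sorted(empty)}")
    return pd.DataFrame(rows)


def population_coverage(changes: pd.DataFrame, region_map: RegionMap, sex: str) -> float:
    """Share of the world population of ``sex`` living in countries with declining mortality."""
    sub = changes[changes["sex"] == sex]
    merged = _with_region(sub, region_map)
    col = f"pop_{sex}"
    if merged[col].isna().any():
        raise ValueError("population missing for some countries")
    total = merged[col].sum()
    declining = merged.loc[merged["delta"] < 0, col].sum()
    return float(declining / total)


def convergence_sd(values: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Within-region sample standard deviation (n-1 denominator) of a country metric.

    ``values`` carries columns country, sex, value (a level or a
    change).  A shrinking SD over time indicates regional convergence.
    Regions with fewer than two countries are omitted with a warning.
    """
    merged = _with_region(values.rename(columns={values.columns[-1]: "value"}), region_map)
    rows = []
    skipped = []
    for (region, sex), grp in merged.groupby(["region", "sex"]):
        if len(grp) < 2:
            skipped.append(region)
            continue
        rows.append(
            {"region": region, "sex": sex, "sd": float(grp["value"].std(ddof=1)), "n": len(grp)}
        )
    if skipped:
        warnings.warn(f"regions with <2 countries omitted: {sorted(set(skipped))}")
    return pd.DataFrame(rows)


def level_change_correlation(changes: pd.DataFrame, levels: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation, per sex, between the period change and its starting level.

    ``changes`` has columns country, sex, delta (pp); ``levels`` has
    country, sex, value (starting-year probability).  Levels are put on
    the percentage scale before correlating (Pearson r is invariant to
    linear rescaling, so this affects nothing but readability).
    """
    merged = changes.merge(levels, on=["country", "sex"])
    rows = []
    for sex, grp in merged.groupby("sex"):
        if len(grp) < 3:
            raise ValueError(f"need >= 3 countries to correlate, got {len(grp)} for {sex}")
        x = grp["delta"].to_numpy()
        y = 100.0 * grp["value"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("correlation undefined: zero variance")
        rows.append({"sex": sex, "r": float(np.corrcoef(x, y)[0, 1]), "n": len(grp)})
    return pd.DataFrame(rows)


def select_benchmark(
    changes: pd.DataFrame,
    region_map: RegionMap,
    eligible: Iterable[str],
    levels: pd.DataFrame | None = None,
    min_countries: int = 3,
) -> pd.DataFrame:
    """Per-region, per-sex benchmark: the eligible country with the largest reduction.

    ``eligible`` is the high-quality subset of the decomposition
    countries; regions contributing fewer than ``min_countries``
    eligible countries get no benchmark.  Ties on the change are broken
    by the higher starting level (``levels``: country, sex, value for
    the first year of the period — the harder starting point wins),
    then alphabetically.
    """
    eligible = set(eligible)
    sub = changes[changes["country"].isin(eligible)]
    merged = _with_region(sub, region_map)
    if levels is not None:
        merged = merged.merge(
            levels.rename(columns={"value": "level"}), on=["country", "sex"], how="left"
        )
    else:
        merged = merged.assign(level=0.0)
    rows = []
    for (region, sex), grp in merged.groupby(["region", "sex"]):
        if grp["country"].nunique() < min_countries:
            rows.append({"region": region, "sex": sex, "benchmark": None, "delta": np.nan})
            continue
        ordered = grp.sort_values(
            ["delta", "level", "country"], ascending=[True, False, True]
        )
        best = ordered.iloc[0]
        rows.append(
            {"region": region, "sex": sex, "benchmark": best["country"], "delta": float(best["delta"])}
        )
    return pd.DataFrame(rows)
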