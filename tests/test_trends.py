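"""Period changes, the decadal classification scheme, and summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncd_decomp import (
    Category,
    RegionMap,
    change,
    change_table,
    classify_decadal,
    convergence_sd,
    level_change_correlation,
    population_coverage,
    region_summary,
    select_benchmark,
)
from ncd_decomp.io import REGIONS


def _prob(records):
    return pd.DataFrame(records, columns=["country", "sex", "year", "value"])


def test_change_is_endpoint_difference_in_percentage_points():
    prob = _prob([("AAA", "female", 2010, 0.50), ("AAA", "female", 2019, 0.41)])
    rec = change(prob, "AAA", "female", 2010, 2019)
    assert rec.delta == pytest.approx(-9.0)
    back = _prob([("AAA", "female", 2010, 0.41), ("AAA", "female", 2019, 0.50)])
    assert change(back, "AAA", "female", 2010, 2019).delta == pytest.approx(9.0)
    same = _prob([("AAA", "female", 2010, 0.4), ("AAA", "female", 2019, 0.4)])
    assert change(same, "AAA", "female", 2010, 2019).delta == 0.0
    with pytest.raises(KeyError):
        change(prob, "AAA", "female", 2001, 2019)


def test_change_table_requires_endpoint_years():
    prob = _prob([("AAA", "female", 2010, 0.5), ("AAA", "female", 2019, 0.4),
                  ("BBB", "female", 2010, 0.3), ("BBB", "female", 2019, 0.35)])
    table = change_table(prob, 2010, 2019)
    assert dict(zip(table["country"], table["delta"])) == pytest.approx(
        {"AAA": -10.0, "BBB": 5.0}
    )
    with pytest.raises(KeyError):
        change_table(prob, 2001, 2019)


@pytest.mark.parametrize(
    "d1, d2, category, direction",
    [
        (-3.0, -9.0, Category.LARGER_DECLINE, "improvement"),
        (3.0, -3.0, Category.REVERSAL_OF_INCREASE, "improvement"),
        (4.0, 1.5, Category.SMALLER_INCREASE, "improvement"),
        (-5.0, -2.0, Category.SMALLER_DECLINE, "deterioration"),
        (-2.0, 2.1, Category.REVERSAL_OF_DECLINE, "deterioration"),
        (2.0, 5.0, Category.LARGER_INCREASE, "deterioration"),
        (-5.0, -5.0, Category.UNCHANGED_PACE, "neutral"),
        (0.0, 0.0, Category.UNCHANGED_PACE, "neutral"),
        (0.0, -1.0, Category.LARGER_DECLINE, "improvement"),
        (0.0, 1.0, Category.LARGER_INCREASE, "deterioration"),
        (-2.0, 0.0, Category.SMALLER_DECLINE, "deterioration"),
        (2.0, 0.0, Category.SMALLER_INCREASE, "improvement"),
    ],
)
def test_classification_truth_table(d1, d2, category, direction):
    got = classify_decadal(d1, d2)
    assert got.category is category
    assert got.direction == direction


@settings(max_examples=500, derandomize=True)
@given(
    st.floats(-60, 60, allow_nan=False, allow_infinity=False),
    st.floats(-60, 60, allow_nan=False, allow_infinity=False),
)
def test_classification_is_total_and_consistent(d1, d2):
    """Every finite pair gets exactly one category with the right direction."""
    got = classify_decadal(d1, d2, atol=0.0)
    assert got.category in Category
    if d2 == d1:
        assert got.direction == "neutral"
    else:
        # verbal scheme: improvement iff the second-period change is more
        # favourable (more negative) than the first, deterioration otherwise
        assert got.direction == ("improvement" if d2 < d1 else "deterioration")


# ---------------------------------------------------------------------
# summaries

def _rmap(countries, region=REGIONS[0], pops=None):
    pops = pops if pops is not None else [1e6] * len(countries)
    return RegionMap(pd.DataFrame({
        "country": countries,
        "region": [region] * len(countries),
        "quality": ["high"] * len(countries),
        "pop_female": pops,
        "pop_male": pops,
    }))


def _changes(countries, deltas, sex="female"):
    return pd.DataFrame({"country": countries, "sex": [sex] * len(countries), "delta": deltas})


def test_region_summary_mean_decline_and_counts():
    rmap = _rmap(["A", "B", "C"])
    out = region_summary(_changes(["A", "B", "C"], [-2.0, -4.0, 3.0]), rmap)
    row = out.iloc[0]
    assert row["mean_decline_pp"] == pytest.approx(1.0)
    assert row["n_declining"] == 2 and row["n_total"] == 3
    assert row["share_declining"] == pytest.approx(2 / 3)

    zero = region_summary(_changes(["A", "B", "C"], [0.0, 0.0, 0.0]), rmap)
    assert zero.iloc[0]["mean_decline_pp"] == 0.0 and zero.iloc[0]["n_declining"] == 0

    single = region_summary(_changes(["A"], [-7.0]), _rmap(["A"]))
    assert single.iloc[0]["mean_decline_pp"] == pytest.approx(7.0)


def test_population_coverage_ratios():
    rmap = _rmap(["A", "B"], pops=[1e6, 1e6])
    assert population_coverage(_changes(["A", "B"], [-1.0, -2.0]), rmap, "female") == 1.0
    half = population_coverage(_changes(["A", "B"], [-1.0, 2.0]), rmap, "female")
    assert half == pytest.approx(0.5)
    scaled = _rmap(["A", "B"], pops=[7e8, 7e8])
    assert population_coverage(_changes(["A", "B"], [-1.0, 2.0]), scaled, "female") == pytest.approx(0.5)


def test_convergence_sd_closed_form_and_translation_invariance():
    rmap = _rmap(["A", "B"])
    vals = pd.DataFrame({"country": ["A", "B"], "sex": ["female"] * 2, "value": [1.0, 3.0]})
    out = convergence_sd(vals, rmap)
    assert out.iloc[0]["sd"] == pytest.approx(np.sqrt(2.0))
    shifted = vals.assign(value=vals["value"] + 10.0)
    assert convergence_sd(shifted, rmap).iloc[0]["sd"] == pytest.approx(np.sqrt(2.0))
    same = vals.assign(value=2.0)
    assert convergence_sd(same, rmap).iloc[0]["sd"] == 0.0


def test_level_change_correlation_cases(rng):
    countries = [f"C{i}" for i in range(400)]
    levels = rng.uniform(0.2, 0.6, 400)
    # perfect negative: change = -level
    chg = pd.DataFrame({"country": countries, "sex": "female", "delta": -100 * levels})
    lev = pd.DataFrame({"country": countries, "sex": "female", "value": levels})
    out = level_change_correlation(chg, lev)
    assert out.iloc[0]["r"] == pytest.approx(-1.0)
    # independent: r near zero
    chg2 = chg.assign(delta=rng.normal(0, 3, 400))
    r = level_change_correlation(chg2, lev).iloc[0]["r"]
    assert abs(r) < 3 / np.sqrt(400)
    # linear rescaling leaves r unchanged
    r_scaled = level_change_correlation(chg2.assign(delta=5 * chg2["delta"] + 2), lev).iloc[0]["r"]
    assert r_scaled == pytest.approx(r, rel=1e-12)
    with pytest.raises(ValueError):
        level_change_correlation(chg.assign(delta=1.0), lev)


def test_select_benchmark_rules():
    rmap = _rmap(["A", "B", "C", "D"])
    changes = _changes(["A", "B", "C", "D"], [-14.8, -9.2, -6.0, -20.0])
    # largest eligible reduction wins; ineligible countries are ignored
    out = select_benchmark(changes, rmap, eligible=["A", "B", "C"])
    assert out.iloc[0]["benchmark"] == "A"
    # too few eligible countries -> no benchmark
    none = select_benchmark(changes, rmap, eligible=["A", "B"])
    assert none.iloc[0]["benchmark"] is None
    # tie broken by the higher starting level, then alphabetically
    tied = _changes(["A", "B", "C"], [-5.0, -5.0, -1.0])
    levels = pd.DataFrame({"country": ["A", "B", "C"], "sex": ["female"] * 3,
                           "value": [0.3, 0.5, 0.4]})
    out = select_benchmark(tied, _rmap(["A", "B", "C"]), eligible=["A", "B", "C"], levels=levels)
    assert out.iloc[0]["benchmark"] == "B"
    flat = select_benchmark(tied, _rmap(["A", "B", "C"]), eligible=["A", "B", "C"])
    assert flat.iloc[0]["benchmark"] == "A"
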