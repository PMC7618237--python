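"""Horiuchi decomposition: exactness properties and pipeline identities."""

import numpy as np
import pytest
from scipy.integrate import quad

from ncd_decomp import (
    aggregate_contributions,
    decompose_change,
    decompose_decadal,
    decompose_gap,
    horiuchi,
    prob_series,
)


def test_identical_populations_give_zero_everywhere():
    x = np.array([0.1, 0.2, 0.3])
    contrib, residual = horiuchi(lambda v: float(np.prod(1 + v)), x, x.copy(), n_steps=5)
    assert (contrib == 0.0).all() and residual == 0.0


@pytest.mark.parametrize("n_steps", [1, 7, 50])
def test_single_changing_covariate_telescopes_exactly(n_steps):
    """One changing covariate gets the whole change, bitwise, for any N."""

    def f(v):
        return float(np.exp(v[0]) + v[1] ** 2 + np.sin(v[2]))

    x1 = np.array([0.5, 1.7, 0.3])
    x2 = np.array([0.5, 1.7, 1.1])
    contrib, residual = horiuchi(f, x1, x2, n_steps=n_steps)
    assert contrib[0] == 0.0 and contrib[1] == 0.0
    assert contrib[2] == f(x2) - f(x1)
    assert residual == 0.0


def test_product_functional_matches_line_integral_limit():
    """f = x1*x2 from (1,2) to (3,4): contributions -> (6, 4)."""
    contrib, residual = horiuchi(lambda v: float(v[0] * v[1]), [1.0, 2.0], [3.0, 4.0], 1000)
    assert contrib[0] == pytest.approx(6.0, abs=1e-5)
    assert contrib[1] == pytest.approx(4.0, abs=1e-5)
    assert contrib.sum() + residual == pytest.approx(10.0, abs=1e-12)


@pytest.mark.parametrize("n_steps", [1, 13])
def test_linear_functional_is_decomposed_exactly(n_steps, rng):
    w = rng.normal(size=6)
    x1 = rng.normal(size=6)
    x2 = rng.normal(size=6)
    contrib, residual = horiuchi(lambda v: float(w @ v), x1, x2, n_steps=n_steps)
    np.testing.assert_allclose(contrib, w * (x2 - x1), rtol=1e-12, atol=1e-14)
    assert abs(residual) < 1e-12


def test_quadrature_oracle_on_smooth_functional(rng):
    """Contributions match numerically integrated partial-derivative line integrals."""

    def f(v):
        return float(np.exp(0.5 * v[0]) * v[1] + np.sin(v[2]) * v[3] + v[4] ** 3)

    grads = [
        lambda v: 0.5 * np.exp(0.5 * v[0]) * v[1],
        lambda v: np.exp(0.5 * v[0]),
        lambda v: np.cos(v[2]) * v[3],
        lambda v: np.sin(v[2]),
        lambda v: 3 * v[4] ** 2,
    ]
    x1 = rng.uniform(0.1, 1.0, 5)
    x2 = rng.uniform(0.1, 1.0, 5)
    delta = x2 - x1
    contrib, _ = horiuchi(f, x1, x2, n_steps=10_000)
    for i in range(5):
        want = quad(lambda t, i=i: grads[i](x1 + t * delta) * delta[i], 0.0, 1.0)[0]
        assert contrib[i] == pytest.approx(want, rel=1e-5, abs=1e-8)


def test_horiuchi_input_contracts():
    with pytest.raises(ValueError, match="equal length"):
        horiuchi(lambda v: 0.0, [1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="non-finite"):
        horiuchi(lambda v: float("nan"), [-1.0, 1.0], [1.0, 2.0])


# ---------------------------------------------------------------------
# pipeline decompositions

def test_within_period_additivity_and_symmetry(three_year_result):
    surface = three_year_result.surface
    country = surface.countries[0]
    prob = prob_series(surface)

    res = decompose_change(surface, country, "female", 2010, 2019, n_steps=40)
    q = prob.set_index(["country", "sex", "year"])["value"]
    target = 100.0 * (q[(country, "female", 2019)] - q[(country, "female", 2010)])
    assert res.contributions.to_numpy().sum() + res.residual == pytest.approx(target, abs=1e-12)

    back = decompose_change(surface, country, "female", 2019, 2010, n_steps=40)
    np.testing.assert_allclose(
        back.contributions.to_numpy(), -res.contributions.to_numpy(), atol=1e-9
    )


def test_decadal_difference_identities(three_year_result):
    surface = three_year_result.surface
    country = surface.countries[3]
    res = decompose_decadal(surface, country, "male", 2001, 2010, 2019, n_steps=30)
    first = decompose_change(surface, country, "male", 2001, 2010, n_steps=30)
    second = decompose_change(surface, country, "male", 2010, 2019, n_steps=30)
    total = res.contributions.to_numpy().sum() + res.residual
    assert total == pytest.approx(second.total - first.total, abs=1e-12)

    # no change in either decade -> all cells exactly zero
    rate = np.array(surface.rate_array)
    ci = surface.countries.index(country)
    rate[ci, :, 1] = rate[ci, :, 0]
    rate[ci, :, 2] = rate[ci, :, 0]
    frozen = surface.with_rates(rate)
    res_same = decompose_decadal(frozen, country, "male", 2001, 2010, 2019, n_steps=10)
    np.testing.assert_allclose(res_same.contributions.to_numpy(), 0.0, atol=1e-15)
    assert res_same.residual == 0.0

    # equal additive rate changes in both decades -> cells cancel to
    # second order (the two decompositions share the same covariate deltas)
    d = 0.05 * rate[ci, :, 0]
    rate[ci, :, 1] = rate[ci, :, 0] - d
    rate[ci, :, 2] = rate[ci, :, 0] - 2 * d
    stepped = surface.with_rates(rate)
    res_step = decompose_decadal(stepped, country, "male", 2001, 2010, 2019, n_steps=10)
    assert res_step.question == "decadal_difference"
    gross = np.abs(
        decompose_change(stepped, country, "male", 2001, 2010, n_steps=10).contributions
    ).to_numpy().sum()
    assert np.abs(res_step.contributions.to_numpy()).sum() < 0.05 * gross


def test_gap_self_and_antisymmetry(three_year_result):
    surface = three_year_result.surface
    a, b = surface.countries[0], surface.countries[1]
    self_gap = decompose_gap(surface, a, a, "female", 2010, 2019, n_steps=10)
    assert (self_gap.contributions.to_numpy() == 0.0).all()
    assert self_gap.residual == 0.0

    ab = decompose_gap(surface, a, b, "female", 2010, 2019, n_steps=20)
    ba = decompose_gap(surface, b, a, "female", 2010, 2019, n_steps=20)
    np.testing.assert_allclose(
        ab.contributions.to_numpy(), -ba.contributions.to_numpy(), atol=1e-15
    )


def test_aggregate_margins_conserve_total(three_year_result):
    surface = three_year_result.surface
    res = decompose_change(surface, surface.countries[5], "male", 2010, 2019, n_steps=20)
    cells = res.contributions.to_numpy().sum()
    assert aggregate_contributions(res, "cause").sum() == pytest.approx(cells, rel=1e-12)
    assert aggregate_contributions(res, "age").sum() == pytest.approx(cells, rel=1e-12)
    age_class = aggregate_contributions(res, "age_class")
    assert set(age_class.index) == {"<15", "15-64", "65-79"}
    assert age_class.sum() == pytest.approx(cells, rel=1e-12)
    with pytest.raises(ValueError):
        aggregate_contributions(res, "continent")


def test_mass_only_in_old_ages_leaves_working_class_empty(three_year_result):
    surface = three_year_result.surface
    country = surface.countries[0]
    rate = np.array(surface.rate_array)
    ci = surface.countries.index(country)
    # make years differ only in bands 65+
    old = surface.grid.band_start >= 65
    rate[ci, 0, 2] = rate[ci, 0, 1]
    rate[ci, 0, 2, old, :] = rate[ci, 0, 1, old, :] * 0.8
    res = decompose_change(surface.with_rates(rate), country, "female", 2010, 2019, n_steps=10)
    margins = aggregate_contributions(res, "age_class")
    assert margins["<15"] == 0.0 and margins["15-64"] == 0.0
    assert margins["65-79"] < 0.0
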