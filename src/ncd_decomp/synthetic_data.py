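"""Synthetic mortality surfaces with known ground truth.

The generator emulates the statistical structure the pipeline assumes
of cause-of-death estimates: Gompertz-like age gradients in all-NCD
death rates, age-varying cause composition (circulatory and dementia
weight rising with age, congenital-type mortality concentrated in
infancy, sex-specific cancers), per-cause log-linear annual trends
that differ between the 2001-10 and 2010-19 periods, country random
effects on levels and trends, and optional Poisson count noise.  Every
scenario returns its ground truth (planted slopes, labels, or
benchmark countries) so parameter recovery is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .causes import CauseMap
from .grids import AgeGrid
from .io import REGIONS, RegionMap
from .lifetable import prob_from_rates
from .surface import SEXES, MortalitySurface
from .trends import Category

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "cause_age_weights",
    "generate_surface",
    "make_improvement_scenario",
    "make_benchmark_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults give 24 countries (8 regions x 3), calendar years
    2001-2019, and baseline Gompertz hazards calibrated so the
    birth-to-80 all-NCD probability sits near the global levels of
    roughly 0.38 (females) and 0.5 (males), with mean trends that
    decline faster in 2001-10 than in 2010-19.
    """

    n_countries_per_region: int = 3
    regions: tuple[str, ...] = REGIONS
    years: tuple[int, ...] = tuple(range(2001, 2020))
    period_break: int = 2010
    #: all-NCD hazard at age 0 (per person-year), by sex
    alpha_female: float = 3.0e-5
    alpha_male: float = 4.5e-5
    #: lognormal coefficient of variation of the country level effect
    alpha_cv: float = 0.25
    #: Gompertz log-hazard slope per year of age
    beta: float = 0.09
    #: mean per-cause log-linear annual trend, first and second period
    slope_period1: float = -0.020
    slope_period2: float = -0.014
    #: spread of cause-specific mean slopes around the period mean
    cause_slope_sd: float = 0.008
    #: per-cause country deviations around the cause slopes
    country_slope_sd: float = 0.006
    #: country-wide trend deviation shared by all causes, drawn per period
    #: (drives between-country variation in decadal improvement/deterioration)
    country_period_sd: float = 0.008
    #: lognormal population per sex: exp(N(log(population_median), population_sigma))
    population_median: float = 8.0e6
    population_sigma: float = 0.9
    #: multiplies person-years (exposure); raise for lower Poisson noise
    exposure_scale: float = 1.0
    with_counts: bool = False
    quality_cycle: tuple[str, ...] = ("high",)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_countries_per_region < 1:
            problems.append("n_countries_per_region must be >= 1")
        if not self.regions or set(self.regions) - set(REGIONS):
            problems.append("regions must be a non-empty subset of the 8 reporting regions")
        if len(self.years) < 2:
            problems.append("need at least two years")
        if self.alpha_female <= 0 or self.alpha_male <= 0:
            problems.append("baseline hazards alpha must be positive")
        if self.exposure_scale <= 0:
            problems.append("exposure_scale must be positive")
        if self.population_median <= 0:
            problems.append("population_median must be positive")
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))


@dataclass(frozen=True)
class ScenarioResult:
    """A generated surface plus its region map and planted ground truth."""

    surface: MortalitySurface
    region_map: RegionMap
    truth: dict = field(default_factory=dict)


#: short synthetic-country prefixes per region
_REGION_CODE = {
    "high_income_western": "HIW",
    "central_eastern_europe": "CEE",
    "central_asia_middle_east_north_africa": "CAM",
    "east_southeast_asia": "ESA",
    "south_asia": "SAS",
    "latin_america_caribbean": "LAC",
    "sub_saharan_africa": "SSA",
    "pacific_islands": "PAC",
}


# ---------------------------------------------------------------------
# cause-by-age composition

def cause_age_weights(grid: AgeGrid, causes: tuple[str, ...], sex: str) -> np.ndarray:
    """Cause-composition weights per band: shape (n_bands, n_causes), rows sum to 1.

    Built-in shapes: circulatory causes and dementias rise with age,
    cancers rise from mid-life, alcohol/cirrhosis peak in working ages,
    the residual NCD group carries a congenital-type infancy component,
    and breast/cervical/prostate cancers are sex-specific.
    """
    mid = grid.band_mid
    n = len(causes)
    w = np.zeros((grid.n_bands, n))

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    shapes = {
        "ischaemic_heart_disease": 3.0 * np.exp(0.020 * mid),
        "stroke": 1.8 * np.exp(0.022 * mid),
        "other_circulatory": 0.9 * np.exp(0.018 * mid),
        "lung_cancer": 1.6 * logistic((mid - 50) / 8),
        "stomach_cancer": 0.5 * logistic((mid - 50) / 10),
        "colorectal_cancer": 0.7 * logistic((mid - 50) / 9),
        "breast_cancer": 1.0 * logistic((mid - 45) / 9) if sex == "female" else np.zeros_like(mid),
        "cervical_cancer": 0.5 * logistic((mid - 40) / 9) if sex == "female" else np.zeros_like(mid),
        "prostate_cancer": 0.8 * logistic((mid - 58) / 7) if sex == "male" else np.zeros_like(mid),
        "pancreatic_cancer": 0.35 * logistic((mid - 55) / 8),
        "liver_cancer": 0.45 * logistic((mid - 48) / 9),
        "other_malignant_neoplasms": 0.9 * logistic((mid - 40) / 12) + 0.05,
        "copd": 1.0 * logistic((mid - 60) / 7),
        "diabetes_ckd": 0.8 * logistic((mid - 50) / 10),
        "kidney_diseases": 0.35 * logistic((mid - 55) / 10),
        "liver_cirrhosis": 0.6 * np.exp(-((mid - 52) ** 2) / (2 * 14**2)),
        "alzheimer_dementias": 2.2 * logistic((mid - 72) / 4),
        "alcohol_use_disorders": (0.35 if sex == "male" else 0.12)
        * np.exp(-((mid - 48) ** 2) / (2 * 12**2)),
        "other_neuropsychiatric": 0.25 + 0.3 * logistic((mid - 65) / 8),
        "other_ncds": 0.4 + 3.0 * np.exp(-mid / 1.5),  # congenital-type infancy component
    }
    for j, cause in enumerate(causes):
        if cause not in shapes:
            raise ValueError(f"no built-in age shape for cause group {cause!r}")
        w[:, j] = shapes[cause]
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------
# core generator

def _pyramid(grid: AgeGrid) -> np.ndarray:
    """Population share per band: width-proportional with a mild old-age taper."""
    share = grid.band_width * np.exp(-0.018 * grid.band_mid)
    return share / share.sum()


def _period_exponents(years: np.ndarray, break_year: int) -> tuple[np.ndarray, np.ndarray]:
    y0 = years.min()
    t1 = np.clip(years - y0, 0, break_year - y0).astype(float)
    t2 = np.clip(years - break_year, 0, None).astype(float)
    return t1, t2


def generate_surface(config: ScenarioConfig, slopes: np.ndarray | None = None) -> ScenarioResult:
    """Generate a complete mortality surface under log-linear cause trends.

    The band all-NCD rate for a country at the first year is
    ``alpha_country * exp(beta * age_mid)``; cell rates split it by the
    age-varying cause composition and evolve as
    ``exp(slope_1 * years_in_period_1 + slope_2 * years_in_period_2)``
    per cause.  ``slopes`` (shape ``(n_countries, n_causes, 2)``)
    overrides the randomly drawn trends; the drawn or supplied slopes
    are returned as ground truth.  With ``with_counts`` deaths are
    Poisson(rate x person-years) and rates are recomputed from counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = AgeGrid.default()
    causes = CauseMap.default().groups
    n_causes = len(causes)

    countries = [
        f"{_REGION_CODE[region]}{i:02d}"
        for region in config.regions
        for i in range(config.n_countries_per_region)
    ]
    n_c = len(countries)
    years = np.array(sorted(config.years))

    if slopes is None:
        cause_means = np.stack(
            [
                config.slope_period1 + rng.normal(0, config.cause_slope_sd, n_causes),
                config.slope_period2 + rng.normal(0, config.cause_slope_sd, n_causes),
            ],
            axis=1,
        )  # (causes, 2)
        slopes = (
            cause_means[None, :, :]
            + rng.normal(0, config.country_slope_sd, (n_c, n_causes, 2))
            + rng.normal(0, config.country_period_sd, (n_c, 1, 2))
        )
    else:
        slopes = np.asarray(slopes, dtype=float)
        if slopes.shape != (n_c, n_causes, 2):
            raise ValueError(f"slopes must have shape {(n_c, n_causes, 2)}, got {slopes.shape}")

    sigma = np.sqrt(np.log1p(config.alpha_cv**2))
    level = np.exp(rng.normal(-sigma**2 / 2, sigma, n_c))  # mean-1 lognormal country effect

    t1, t2 = _period_exponents(years, config.period_break)
    trend = np.exp(
        slopes[:, None, :, 0] * t1[None, :, None] + slopes[:, None, :, 1] * t2[None, :, None]
    )  # (country, year, cause)

    alpha = {"female": config.alpha_female, "male": config.alpha_male}
    gomp = np.exp(config.beta * grid.band_mid)  # (band,)
    rate = np.empty((n_c, len(SEXES), len(years), grid.n_bands, n_causes))
    for s_idx, sex in enumerate(SEXES):
        w = cause_age_weights(grid, causes, sex)  # (band, cause)
        base = alpha[sex] * level[:, None] * gomp[None, :]  # (country, band)
        rate[:, s_idx] = (
            base[:, None, :, None]  # (country, 1, band, 1)
            * w[None, None, :, :]  # (1, 1, band, cause)
            * trend[:, :, None, :]  # (country, year, 1, cause)
        )

    pops = np.exp(
        rng.normal(np.log(config.population_median), config.population_sigma, (n_c, 2))
    )
    region_map = RegionMap(
        pd.DataFrame(
            {
                "country": countries,
                "region": [r for r in config.regions for _ in range(config.n_countries_per_region)],
                "quality": [
                    config.quality_cycle[i % len(config.quality_cycle)] for i in range(n_c)
                ],
                "pop_female": pops[:, 0],
                "pop_male": pops[:, 1],
            }
        )
    )

    truth = {"slopes": slopes, "causes": causes, "countries": countries, "seed": config.seed}

    if config.with_counts:
        share = _pyramid(grid)
        py = np.empty_like(rate)
        for s_idx, sex in enumerate(SEXES):
            py[:, s_idx] = np.broadcast_to(
                pops[:, s_idx, None, None, None] * share[None, None, :, None] * config.exposure_scale,
                (n_c, len(years), grid.n_bands, n_causes),
            )
        deaths = rng.poisson(rate * py).astype(float)
        surface = MortalitySurface(
            deaths / py, countries, SEXES, years, grid, causes, deaths, py
        )
        truth["expected_rate"] = rate
    else:
        surface = MortalitySurface(rate, countries, SEXES, years, grid, causes)
    return ScenarioResult(surface, region_map, truth)


# ---------------------------------------------------------------------
# planted-classification scenario

#: target (delta1, delta2) percentage-point pairs, each at least 0.5 pp
#: from every boundary of its category region
_CATEGORY_TARGETS = {
    Category.LARGER_DECLINE: (-3.0, -7.0),
    Category.REVERSAL_OF_INCREASE: (3.0, -3.0),
    Category.SMALLER_INCREASE: (4.0, 1.5),
    Category.SMALLER_DECLINE: (-5.0, -2.0),
    Category.REVERSAL_OF_DECLINE: (-3.0, 3.0),
    Category.LARGER_INCREASE: (2.0, 5.0),
    Category.UNCHANGED_PACE: (-3.0, -3.0),
}


def _scale_for_target(base_rates: np.ndarray, grid: AgeGrid, target_q: float) -> float:
    if not 1e-9 < target_q < 1 - 1e-9:
        raise ValueError(f"target probability {target_q:.4f} outside (0, 1): infeasible scenario")
    band = base_rates.sum(axis=1)

    def g(s: float) -> float:
        return float(prob_from_rates(s * band, grid)) - target_q

    return brentq(g, 1e-12, 1e12, xtol=1e-300, rtol=8.9e-16)


def make_improvement_scenario(
    config: ScenarioConfig, targets: dict[str, Category] | None = None
) -> ScenarioResult:
    """Surface whose countries land in prescribed decadal categories.

    Each country's rates are scaled (uniformly over causes and ages,
    log-linearly within each period) so its 2001-10 and 2010-19 changes
    hit the category's target pair; the pair sits at least 0.5 pp from
    every category boundary (the unchanged-pace tie is planted exactly,
    to solver precision).  ``targets`` defaults to cycling all seven
    categories over the countries.  Ground truth: ``truth["labels"]``.
    """
    config.validate()
    years = np.array(sorted(config.years))
    if config.period_break not in years or not years.min() < config.period_break < years.max():
        raise ValueError("scenario years must include the period break strictly inside the range")
    base = generate_surface(replace(config, with_counts=False),
                            slopes=np.zeros((len(config.regions) * config.n_countries_per_region,
                                             20, 2)))
    surface, region_map = base.surface, base.region_map
    countries = surface.countries
    cats = list(_CATEGORY_TARGETS)
    if targets is None:
        targets = {c: cats[i % len(cats)] for i, c in enumerate(countries)}
    unknown = sorted(set(targets) - set(countries))
    if unknown:
        raise ValueError(f"target countries not in scenario: {unknown}")

    grid = surface.grid
    rate = np.array(surface.rate_array)
    y0, y1, y2 = int(years.min()), int(config.period_break), int(years.max())
    t1_all, t2_all = _period_exponents(years, config.period_break)
    span1, span2 = t1_all.max(), t2_all.max()
    labels = {}
    for ci, country in enumerate(countries):
        cat = targets.get(country, cats[ci % len(cats)])
        d1, d2 = _CATEGORY_TARGETS[cat]
        labels[country] = cat
        for si in range(len(surface.sexes)):
            base_block = rate[ci, si, list(surface.years).index(y0)]
            q0 = float(prob_from_rates(base_block.sum(axis=1), grid))
            s1 = _scale_for_target(base_block, grid, q0 + d1 / 100.0)
            q1 = float(prob_from_rates(s1 * base_block.sum(axis=1), grid))
            if cat is Category.UNCHANGED_PACE:
                target2 = 2 * q1 - q0  # exact tie with the achieved first-period change
            else:
                target2 = q1 + d2 / 100.0
            s2 = _scale_for_target(base_block, grid, target2) / s1
            for yi, year in enumerate(surface.years):
                scale = s1 ** (t1_all[yi] / span1) * s2 ** (t2_all[yi] / span2 if span2 else 0.0)
                rate[ci, si, yi] = scale * base_block
    out = MortalitySurface(rate, countries, surface.sexes, surface.years, grid, surface.causes)
    return ScenarioResult(out, region_map, {"labels": labels, "seed": config.seed})


# ---------------------------------------------------------------------
# planted-benchmark scenario

def make_benchmark_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Surface with one planted best-performing country per region.

    Within a region all countries share baseline levels and first-period
    trends; one randomly chosen country is given a uniformly steeper
    2010-19 decline in every cause, so it has the region's largest
    reduction and every other country's benchmark-gap margin is
    non-negative in every cause column.  Requires >= 3 countries per
    region; all countries are high quality.  Ground truth:
    ``truth["benchmarks"]`` (region -> country).
    """
    config.validate()
    if config.n_countries_per_region < 3:
        raise ValueError("benchmark scenario needs >= 3 countries per region")
    rng = np.random.default_rng(config.seed)
    n_regions = len(config.regions)
    n_per = config.n_countries_per_region
    n_c = n_regions * n_per
    n_causes = 20

    slopes = np.empty((n_c, n_causes, 2))
    planted = {}
    for r in range(n_regions):
        block = slice(r * n_per, (r + 1) * n_per)
        slope1 = config.slope_period1 + rng.normal(0, config.cause_slope_sd, n_causes)
        others2 = rng.uniform(-0.018, -0.004, (n_per, n_causes))
        slopes[block, :, 0] = slope1[None, :]
        slopes[block, :, 1] = others2
        b = int(rng.integers(n_per))
        slopes[block, :, 1][b] = others2.min(axis=0) - 0.015  # steeper in every cause
        planted[config.regions[r]] = r * n_per + b

    # shared baseline within region: neutralise country level effects by
    # generating with zero level spread and high quality throughout
    cfg = replace(config, alpha_cv=0.0, with_counts=False, quality_cycle=("high",))
    result = generate_surface(cfg, slopes=slopes)
    benchmarks = {region: result.surface.countries[idx] for region, idx in planted.items()}
    truth = dict(result.truth)
    truth["benchmarks"] = benchmarks
    return ScenarioResult(result.surface, result.region_map, truth)
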