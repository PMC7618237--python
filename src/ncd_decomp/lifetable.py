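"""Unconditional probability of death from an abridged lifetable.

The outcome measure is the probability of dying from a set of causes
between two exact ages *in the absence of competing causes of death*:
a function of the age-specific death rates from the causes of interest
only.  Band death rates are converted to conditional probabilities of
dying with the standard abridged-lifetable (graduation) formula

    q = n * m / (1 + (n - ax) * m)

where ``n`` is the band width in years, ``m`` the death rate, and
``ax`` the separation factor (years lived in the band by those dying
in it; n/2 by default).  The unconditional probability over an age
range is 1 minus the product of the band survival factors (1 - q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import AgeGrid
from .surface import MortalitySurface

__all__ = [
    "band_prob",
    "prob_from_rates",
    "UnconditionalProbability",
    "unconditional_prob",
    "sdg_variant_prob",
    "prob_series",
]


def band_prob(m, n, ax):
    """Conditional probability of dying within a band, from the band rate.

    ``q = n*m / (1 + (n - ax)*m)``; vectorised over its arguments.
    ``q`` is 0 at m = 0 and approaches (never reaches) 1 as m grows.

    Raises
    ------
    ValueError
        For negative rates or ``ax`` outside ``(0, n)``.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    ax = np.asarray(ax, dtype=float)
    if np.any(m < 0) or not np.isfinite(m).all():
        raise ValueError("death rates must be finite and non-negative")
    if np.any(ax <= 0) or np.any(ax >= n):
        raise ValueError("separation factor ax must satisfy 0 < ax < n")
    q = n * m / (1.0 + (n - ax) * m)
    return q if q.ndim else float(q)


def prob_from_rates(band_rates: np.ndarray, grid: AgeGrid) -> np.ndarray | float:
    """Unconditional probability over the whole grid from all-cause band rates.

    ``band_rates`` has shape ``(..., n_bands)``; leading axes broadcast,
    so a batch of rate vectors is evaluated in one call.
    """
    band_rates = np.asarray(band_rates, dtype=float)
    if band_rates.shape[-1] != grid.n_bands:
        raise ValueError(
            f"expected {grid.n_bands} band rates on the last axis, got {band_rates.shape[-1]}"
        )
    q = band_prob(band_rates, grid.band_width, grid.ax)
    value = 1.0 - np.prod(1.0 - np.asarray(q), axis=-1)
    return value if np.ndim(value) else float(value)


@dataclass(frozen=True)
class UnconditionalProbability:
    """Probability of dying from ``cause_set`` between ``age_lo`` and ``age_hi``."""

    value: float
    country: str
    sex: str
    year: int
    cause_set: tuple[str, ...]
    age_lo: float
    age_hi: float


def _resolve_causes(surface: MortalitySurface, cause_set: Iterable[str] | None) -> list[int]:
    if cause_set is None:
        return list(range(len(surface.causes)))
    causes = list(cause_set)
    if not causes:
        raise ValueError("cause_set must not be empty")
    unknown = sorted(set(causes) - set(surface.causes))
    if unknown:
        raise ValueError(f"cause groups not on the surface: {unknown}")
    return [surface.causes.index(c) for c in causes]


def unconditional_prob(
    surface: MortalitySurface,
    country: str,
    sex: str,
    year: int,
    cause_set: Iterable[str] | None = None,
    age_lo: float = 0.0,
    age_hi: float = 80.0,
) -> UnconditionalProbability:
    """Probability of dying from ``cause_set`` between two exact ages.

    Competing causes are excluded by construction: only rates of the
    requested cause groups within ``[age_lo, age_hi)`` enter the
    calculation.  ``cause_set=None`` means all groups on the surface.
    The age range must tile exactly onto grid band edges.
    """
    cols = _resolve_causes(surface, cause_set)
    sl, sub = surface.grid.window(age_lo, age_hi)
    rates = surface.rates(country, sex, year)[sl][:, cols].sum(axis=1)
    value = float(prob_from_rates(rates, sub))
    names = tuple(surface.causes[i] for i in cols)
    return UnconditionalProbability(value, country, sex, int(year), names, age_lo, age_hi)


def sdg_variant_prob(
    surface: MortalitySurface,
    country: str,
    sex: str,
    year: int,
    sdg_causes: Sequence[str],
) -> UnconditionalProbability:
    """SDG-3.4 restricted variant: ages 30-70, SDG-tagged cause groups only.

    ``sdg_causes`` is the SDG cause superset from the cause map
    (``CauseMap.sdg_groups``): cancers, cardiovascular diseases,
    chronic respiratory diseases, and diabetes.
    """
    if not list(sdg_causes):
        raise ValueError("the SDG cause set is empty; tag groups with sdg34 in the cause map")
    return unconditional_prob(
        surface, country, sex, year, cause_set=sdg_causes, age_lo=30.0, age_hi=70.0
    )


def prob_series(
    surface: MortalitySurface,
    cause_set: Iterable[str] | None = None,
    age_lo: float = 0.0,
    age_hi: float = 80.0,
) -> pd.DataFrame:
    """One unconditional probability per (country, sex, year) on the surface.

    Returns a tidy frame with columns country, sex, year, value,
    ordered by the surface index; deterministic and independent of the
    input row order used to build the surface.
    """
    cols = _resolve_causes(surface, cause_set)
    sl, sub = surface.grid.window(age_lo, age_hi)
    band_rates = surface.rate_array[:, :, :, sl, :][..., cols].sum(axis=-1)
    values = prob_from_rates(band_rates, sub)
    idx = pd.MultiIndex.from_product(
        [surface.countries, surface.sexes, surface.years],
        names=["country", "sex", "year"],
    )
    return pd.DataFrame({"value": np.asarray(values).ravel()}, index=idx).reset_index()
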