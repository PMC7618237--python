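"""Horiuchi decomposition of changes in the probability of death.

The Horiuchi method attributes a difference ``f(x2) - f(x1)`` of a
scalar functional of many covariates to the individual covariates, by
moving along the straight line from ``x1`` to ``x2`` in ``N`` equal
sub-intervals and, within each sub-interval, measuring the effect of
changing one covariate over its sub-interval span while all others sit
at the sub-interval midpoint.  The sum of contributions differs from
the total change by a residual that shrinks as N^-2; the residual is
reported, never redistributed.

Here the covariates are the death rates per (age band, cause group)
and the functional is 100 x the unconditional probability of dying
from all NCDs between birth and age 80.  Three questions are answered:

- within-period: which causes/ages drove the change over one period;
- decadal difference: which causes/ages drove the difference between
  the 2010-19 and 2001-10 changes (difference of the two within-period
  decompositions, cellwise);
- benchmark gap: which causes/ages explain a country's 2010-19
  performance gap to its regional benchmark (difference of the two
  countries' within-period decompositions, cellwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .lifetable import prob_from_rates
from .surface import MortalitySurface

__all__ = [
    "horiuchi",
    "DecompositionResult",
    "decompose_change",
    "decompose_decadal",
    "decompose_gap",
    "aggregate_contributions",
]

#: rows per batched function evaluation (memory / speed trade-off)
_CHUNK_ROWS = 200_000


def horiuchi(
    f: Callable[[np.ndarray], float],
    x1: np.ndarray,
    x2: np.ndarray,
    n_steps: int = 100,
    batch: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-covariate contributions to ``f(x2) - f(x1)`` along a linear path.

    Parameters
    ----------
    f
        Scalar functional of a covariate vector.  With ``batch=True``
        it must accept an array of shape ``(k, len(x))`` and return
        ``k`` values; this is much faster for vectorisable functionals.
    x1, x2
        Covariate vectors of equal length.
    n_steps
        Number of sub-intervals N (>= 1).

    Returns
    -------
    contributions, residual
        ``contributions[i]`` is covariate i's share of the change;
        covariates with ``x1[i] == x2[i]`` contribute exactly 0.
        ``residual = (f(x2) - f(x1)) - contributions.sum()``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError(f"x1 and x2 must be 1-d and equal length, got {x1.shape} vs {x2.shape}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")

    if batch:
        fb = lambda rows: np.asarray(f(rows), dtype=float)  # noqa: E731
    else:
        fb = lambda rows: np.array([f(r) for r in rows], dtype=float)  # noqa: E731

    ends = fb(np.vstack([x1, x2]))
    if not np.isfinite(ends).all():
        raise ValueError("f is non-finite at an endpoint")
    total = float(ends[1] - ends[0])

    delta = x2 - x1
    active = np.flatnonzero(delta)
    k = x1.size
    contrib = np.zeros(k)
    if active.size:
        a = active.size
        n = int(n_steps)
        # chunk the steps so each batched evaluation stays bounded in memory
        steps_per_chunk = max(1, _CHUNK_ROWS // max(1, 2 * a))
        for j0 in range(1, n + 1, steps_per_chunk):
            j = np.arange(j0, min(j0 + steps_per_chunk, n + 1))
            c = j.size
            mid = x1 + ((j - 0.5) / n)[:, None] * delta  # (c, k)
            upper = np.broadcast_to(mid[:, None, :], (c, a, k)).copy()
            lower = upper.copy()
            rows = np.arange(a)
            upper[:, rows, active] = x1[active] + (j / n)[:, None] * delta[active]
            lower[:, rows, active] = x1[active] + ((j - 1) / n)[:, None] * delta[active]
            fu = fb(upper.reshape(-1, k)).reshape(c, a)
            fl = fb(lower.reshape(-1, k)).reshape(c, a)
            if not (np.isfinite(fu).all() and np.isfinite(fl).all()):
                bad = int(j[np.argwhere(~np.isfinite(fu - fl))[0][0]])
                raise ValueError(f"f returned a non-finite value at step {bad}")
            contrib[active] += (fu - fl).sum(axis=0)
    residual = total - float(contrib.sum())
    return contrib, residual


# ---------------------------------------------------------------------
# pipeline decompositions

@dataclass(frozen=True)
class DecompositionResult:
    """Cause x age contributions (percentage points) for one question.

    ``contributions`` is a frame indexed by band start age with one
    column per cause group; ``contributions.sum().sum() + residual``
    equals the target difference by construction.
    """

    contributions: pd.DataFrame
    residual: float
    steps: int
    question: str  # within_period | decadal_difference | benchmark_gap
    endpoints: dict

    @property
    def total(self) -> float:
        return float(self.contributions.to_numpy().sum() + self.residual)


def _prob_functional(sub_grid, n_causes: int) -> Callable[[np.ndarray], np.ndarray]:
    n_bands = sub_grid.n_bands

    def f(rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        band = rows.reshape(rows.shape[0], n_bands, n_causes).sum(axis=2)
        return 100.0 * np.asarray(prob_from_rates(band, sub_grid))

    return f


def decompose_change(
    surface: MortalitySurface,
    country: str,
    sex: str,
    year_a: int,
    year_b: int,
    cause_set: Iterable[str] | None = None,
    age_lo: float = 0.0,
    age_hi: float = 80.0,
    n_steps: int = 100,
) -> DecompositionResult:
    """Within-period decomposition of the change from ``year_a`` to ``year_b``.

    The functional is 100 x the unconditional probability of dying
    from ``cause_set`` (default: all groups) between ``age_lo`` and
    ``age_hi``; the covariates are the (band, cause) rates of the two
    years.  Contributions are on the percentage-point scale.
    """
    causes = list(cause_set) if cause_set is not None else list(surface.causes)
    unknown = sorted(set(causes) - set(surface.causes))
    if unknown:
        raise ValueError(f"cause groups not on the surface: {unknown}")
    cols = [surface.causes.index(c) for c in causes]
    sl, sub = surface.grid.window(age_lo, age_hi)

    x1 = surface.rates(country, sex, year_a)[sl][:, cols].ravel()
    x2 = surface.rates(country, sex, year_b)[sl][:, cols].ravel()
    f = _prob_functional(sub, len(cols))
    contrib, residual = horiuchi(f, x1, x2, n_steps=n_steps, batch=True)
    table = pd.DataFrame(
        contrib.reshape(sub.n_bands, len(cols)),
        index=pd.Index(sub.band_start, name="age_start"),
        columns=pd.Index(causes, name="cause"),
    )
    return DecompositionResult(
        table,
        residual,
        int(n_steps),
        "within_period",
        {"country": country, "sex": sex, "year_a": int(year_a), "year_b": int(year_b),
         "age_lo": age_lo, "age_hi": age_hi},
    )


def decompose_decadal(
    surface: MortalitySurface,
    country: str,
    sex: str,
    year_0: int = 2001,
    year_1: int = 2010,
    year_2: int = 2019,
    cause_set: Iterable[str] | None = None,
    age_lo: float = 0.0,
    age_hi: float = 80.0,
    n_steps: int = 100,
) -> DecompositionResult:
    """Decadal-difference decomposition: (change y1->y2) minus (change y0->y1).

    Computed as the cellwise difference of the two within-period
    decompositions, so the cells plus the differenced residual add up
    exactly to delta2 - delta1.  Negative cells are contributions to
    improvement (a faster decline), positive to deterioration.
    """
    second = decompose_change(
        surface, country, sex, year_1, year_2, cause_set, age_lo, age_hi, n_steps
    )
    first = decompose_change(
        surface, country, sex, year_0, year_1, cause_set, age_lo, age_hi, n_steps
    )
    return DecompositionResult(
        second.contributions - first.contributions,
        second.residual - first.residual,
        int(n_steps),
        "decadal_difference",
        {"country": country, "sex": sex,
         "year_0": int(year_0), "year_1": int(year_1), "year_2": int(year_2),
         "age_lo": age_lo, "age_hi": age_hi},
    )


def decompose_gap(
    surface: MortalitySurface,
    country: str,
    benchmark_country: str,
    sex: str,
    year_a: int = 2010,
    year_b: int = 2019,
    cause_set: Iterable[str] | None = None,
    age_lo: float = 0.0,
    age_hi: float = 80.0,
    n_steps: int = 100,
) -> DecompositionResult:
    """Benchmark-gap decomposition: country's change minus the benchmark's.

    Positive cells mark causes/ages where the country lags the
    benchmark (smaller decline or larger increase).
    """
    own = decompose_change(surface, country, sex, year_a, year_b, cause_set, age_lo, age_hi, n_steps)
    ref = decompose_change(
        surface, benchmark_country, sex, year_a, year_b, cause_set, age_lo, age_hi, n_steps
    )
    return DecompositionResult(
        own.contributions - ref.contributions,
        own.residual - ref.residual,
        int(n_steps),
        "benchmark_gap",
        {"country": country, "benchmark": benchmark_country, "sex": sex,
         "year_a": int(year_a), "year_b": int(year_b), "age_lo": age_lo, "age_hi": age_hi},
    )


#: age classes used in the narrative: children, working ages, older ages
_AGE_CLASSES = (("<15", 0.0, 15.0), ("15-64", 15.0, 65.0), ("65-79", 65.0, 80.0))


def aggregate_contributions(result: DecompositionResult, by: str) -> pd.Series:
    """Marginal totals of a decomposition: by cause, age band, or age class.

    Age classes pool bands into <15, 15-64 (working ages), and 65-79
    (older ages).  Every margin sums to the same grand total (the sum
    of all cells).
    """
    table = result.contributions
    if by == "cause":
        return table.sum(axis=0)
    if by == "age":
        return table.sum(axis=1)
    if by == "age_class":
        band_totals = table.sum(axis=1)
        starts = band_totals.index.to_numpy(dtype=float)
        out = {}
        for label, lo, hi in _AGE_CLASSES:
            out[label] = float(band_totals[(starts >= lo) & (starts < hi)].sum())
        return pd.Series(out, name="contribution_pp")
    raise ValueError(f"unknown margin {by!r}; use 'cause', 'age', or 'age_class'")
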