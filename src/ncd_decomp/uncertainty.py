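"""Monte-Carlo uncertainty propagation via replicate mortality surfaces.

The default mechanism resamples death counts cell-by-cell as
Poisson(observed deaths), recomputes rates, and pushes each replicate
surface through the statistic of interest; the 95% uncertainty
interval (UI) is the 2.5th-97.5th percentile range over replicates
(linear-interpolation percentile rule).  Externally produced replicate
rate sets can be wrapped in the same :class:`DrawSet` interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .surface import MortalitySurface

__all__ = ["DrawSet", "UncertaintyInterval", "make_poisson_draws", "ui", "ui_excludes_zero"]


@dataclass(frozen=True)
class DrawSet:
    """Replicate rate arrays around a central surface.

    ``rates`` has shape ``(n_draws,) + base.shape``; every draw is a
    valid surface over the same index.  The seed that produced the
    draws is recorded for reproducibility.
    """

    base: MortalitySurface
    rates: np.ndarray
    seed: int | None

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 6 or rates.shape[1:] != self.base.shape:
            raise ValueError(
                f"draw rates must have shape (n_draws,)+{self.base.shape}, got {rates.shape}"
            )
        if rates.shape[0] < 2:
            raise ValueError("need at least 2 draws")
        if not np.isfinite(rates).all() or (rates < 0).any():
            raise ValueError("draw rates must be finite and non-negative")
        object.__setattr__(self, "rates", rates)

    @property
    def n_draws(self) -> int:
        return int(self.rates.shape[0])

    def surfaces(self) -> Iterator[MortalitySurface]:
        for d in range(self.n_draws):
            yield self.base.with_rates(self.rates[d])


def make_poisson_draws(surface: MortalitySurface, n_draws: int = 1000, seed: int = 0) -> DrawSet:
    """Poisson-resample death counts independently per cell and recompute rates.

    Requires the surface to carry counts.  Cells with zero observed
    deaths stay zero in every draw.  Deterministic given ``seed``.
    """
    if not surface.has_counts:
        raise ValueError("Poisson draws need death counts and person-years on the surface")
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    rng = np.random.default_rng(seed)
    deaths = surface.deaths_array
    py = surface.person_years_array
    drawn = rng.poisson(lam=deaths, size=(int(n_draws),) + deaths.shape).astype(float)
    return DrawSet(surface, drawn / py, int(seed))


@dataclass(frozen=True)
class UncertaintyInterval:
    point: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValueError(f"interval bounds out of order: ({self.lo}, {self.hi})")


def ui(
    statistic: Callable[[MortalitySurface], float],
    drawset: DrawSet,
    level: float = 0.95,
) -> UncertaintyInterval:
    """Point estimate on the central surface plus a percentile interval over draws.

    The bounds are the (1-level)/2 and 1-(1-level)/2 percentiles of the
    draw statistics under numpy's linear-interpolation percentile rule.
    """
    point = float(statistic(drawset.base))
    vals = np.empty(drawset.n_draws)
    for d, s in enumerate(drawset.surfaces()):
        v = float(statistic(s))
        if not np.isfinite(v):
            raise ValueError(f"statistic non-finite on draw {d}")
        vals[d] = v
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [tail, 100.0 - tail], method="linear")
    return UncertaintyInterval(point, float(lo), float(hi))


def ui_excludes_zero(interval: UncertaintyInterval) -> bool:
    """True iff the interval lies strictly on one side of zero.

    An interval excluding zero marks a change distinct from no change
    at the interval's confidence level.
    """
    return interval.lo > 0.0 or interval.hi < 0.0
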