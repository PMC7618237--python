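"""Abridged-lifetable age grids.

An :class:`AgeGrid` is a set of contiguous, half-open age bands
``[start, start + width)`` together with a separation factor ``ax`` per
band — the average number of years lived within the band by those who
die in it.  The default analysis grid covers exact ages 0 to 80 with an
infant band [0,1), a childhood band [1,5), and fifteen 5-year bands;
the SDG-3.4 variant covers ages 30 to 70 with eight 5-year bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeGrid"]


@dataclass(frozen=True)
class AgeGrid:
    """Contiguous half-open age bands with per-band separation factors.

    Parameters
    ----------
    band_start
        Exact age in years at which each band opens, ascending.
    band_width
        Width of each band in years.
    ax
        Average years lived in the band by those dying in it; must
        satisfy ``0 < ax < width``.  Defaults to ``width / 2`` (the
        mid-band convention used by the WHO SDG-3.4 lifetable method).
    """

    band_start: np.ndarray
    band_width: np.ndarray
    ax: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        start = np.asarray(self.band_start, dtype=float)
        width = np.asarray(self.band_width, dtype=float)
        if start.ndim != 1 or start.shape != width.shape or start.size == 0:
            raise ValueError("band_start and band_width must be equal-length 1-d arrays")
        if np.any(width <= 0):
            raise ValueError("band widths must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("band starts must be strictly ascending")
        if not np.allclose(start[1:], (start + width)[:-1]):
            raise ValueError("bands must be contiguous: each band must end where the next starts")
        ax = self.ax
        ax = width / 2.0 if ax is None else np.asarray(ax, dtype=float)
        if ax.shape != width.shape or np.any(ax <= 0) or np.any(ax >= width):
            raise ValueError("ax must satisfy 0 < ax < width for every band")
        object.__setattr__(self, "band_start", start)
        object.__setattr__(self, "band_width", width)
        object.__setattr__(self, "ax", ax)

    # -- constructors -------------------------------------------------

    @classmethod
    def default(cls) -> "AgeGrid":
        """Grid covering [0, 80): [0,1), [1,5), then 5-year bands to [75,80)."""
        starts = [0.0, 1.0] + [float(a) for a in range(5, 80, 5)]
        widths = [1.0, 4.0] + [5.0] * 15
        return cls(np.array(starts), np.array(widths))

    @classmethod
    def sdg(cls) -> "AgeGrid":
        """Grid covering [30, 70) in eight 5-year bands (SDG target 3.4 ages)."""
        starts = np.array([float(a) for a in range(30, 70, 5)])
        return cls(starts, np.full(8, 5.0))

    # -- properties ---------------------------------------------------

    @property
    def n_bands(self) -> int:
        return int(self.band_start.size)

    @property
    def age_lo(self) -> float:
        return float(self.band_start[0])

    @property
    def age_hi(self) -> float:
        return float(self.band_start[-1] + self.band_width[-1])

    @property
    def band_mid(self) -> np.ndarray:
        return self.band_start + self.band_width / 2.0

    def labels(self) -> list[str]:
        """Human-readable band labels, e.g. ``"0"``, ``"1-4"``, ``"75-79"``."""
        out = []
        for s, w in zip(self.band_start, self.band_width):
            if w == 1:
                out.append(f"{s:g}")
            else:
                out.append(f"{s:g}-{s + w - 1:g}")
        return out

    # -- subsetting ---------------------------------------------------

    def window(self, age_lo: float, age_hi: float) -> tuple[slice, "AgeGrid"]:
        """Band slice and sub-grid covering exactly ``[age_lo, age_hi)``.

        Raises
        ------
        ValueError
            If either age does not fall on a band edge of this grid.
        """
        if age_hi <= age_lo:
            raise ValueError(f"empty age range [{age_lo}, {age_hi})")
        edges = np.append(self.band_start, self.age_hi)
        ilo = np.searchsorted(edges, age_lo)
        ihi = np.searchsorted(edges, age_hi)
        if ilo >= len(edges) or edges[ilo] != age_lo or ihi >= len(edges) or edges[ihi] != age_hi:
            raise ValueError(
                f"age range [{age_lo}, {age_hi}) is not aligned to band edges {edges.tolist()}"
            )
        sl = slice(int(ilo), int(ihi))
        sub = AgeGrid(self.band_start[sl], self.band_width[sl], self.ax[sl])
        return sl, sub
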