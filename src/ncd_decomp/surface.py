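"""The mortality surface: death rates by country, sex, year, age band, cause group.

A :class:`MortalitySurface` is the pipeline's sole substantive input.
It stores cause- and age-specific NCD death rates (deaths per
person-year) on a complete index — every (country, sex, year) block
carries every age band and every cause group, with explicit zeros.
Counts (deaths, person-years) are optional and required only for
Poisson uncertainty draws.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import AgeGrid

__all__ = ["MortalitySurface", "SEXES"]

SEXES = ("female", "male")

#: relative tolerance for the rate == deaths / person_years consistency check
_RATE_RTOL = 1e-12


class MortalitySurface:
    """Complete panel of death rates indexed by (country, sex, year, band, cause).

    Internally the rates are held as a dense 5-d array
    ``(country, sex, year, band, cause)`` for fast block access; the
    long tidy form is available through :meth:`to_frame`.
    """

    def __init__(
        self,
        rate: np.ndarray,
        countries: Sequence[str],
        sexes: Sequence[str],
        years: Sequence[int],
        grid: AgeGrid,
        causes: Sequence[str],
        deaths: np.ndarray | None = None,
        person_years: np.ndarray | None = None,
    ) -> None:
        rate = np.asarray(rate, dtype=float)
        shape = (len(countries), len(sexes), len(years), grid.n_bands, len(causes))
        if rate.shape != shape:
            raise ValueError(f"rate array has shape {rate.shape}, expected {shape}")
        if not np.isfinite(rate).all():
            raise ValueError("rates must all be finite")
        if (rate < 0).any():
            raise ValueError("rates must all be non-negative")
        if (deaths is None) != (person_years is None):
            raise ValueError("deaths and person_years must be supplied together")
        if deaths is not None:
            deaths = np.asarray(deaths, dtype=float)
            person_years = np.asarray(person_years, dtype=float)
            if deaths.shape != shape or person_years.shape != shape:
                raise ValueError("deaths/person_years must match the rate array shape")
            if (deaths < 0).any():
                raise ValueError("death counts must be non-negative")
            if (person_years <= 0).any():
                raise ValueError("person_years must be positive")
            implied = deaths / person_years
            if not np.allclose(rate, implied, rtol=_RATE_RTOL, atol=1e-300):
                bad = int(np.sum(~np.isclose(rate, implied, rtol=_RATE_RTOL, atol=1e-300)))
                raise ValueError(
                    f"rate != deaths/person_years beyond {_RATE_RTOL} relative tolerance in {bad} cells"
                )
        self._rate = rate
        self._deaths = deaths
        self._py = person_years
        self.countries = tuple(countries)
        self.sexes = tuple(sexes)
        self.years = tuple(int(y) for y in years)
        self.grid = grid
        self.causes = tuple(causes)
        self._ci = {c: i for i, c in enumerate(self.countries)}
        self._si = {s: i for i, s in enumerate(self.sexes)}
        self._yi = {y: i for i, y in enumerate(self.years)}

    # -- basic access -------------------------------------------------

    @property
    def has_counts(self) -> bool:
        return self._deaths is not None

    @property
    def shape(self) -> tuple[int, ...]:
        return self._rate.shape

    def _loc(self, country: str, sex: str, year: int) -> tuple[int, int, int]:
        try:
            return self._ci[country], self._si[sex], self._yi[int(year)]
        except KeyError as err:
            raise KeyError(f"no block for (country={country!r}, sex={sex!r}, year={year})") from err

    def rates(self, country: str, sex: str, year: int) -> np.ndarray:
        """Rate matrix of shape (n_bands, n_causes) for one block (a copy)."""
        i, j, k = self._loc(country, sex, year)
        return self._rate[i, j, k].copy()

    def counts(self, country: str, sex: str, year: int) -> tuple[np.ndarray, np.ndarray]:
        if not self.has_counts:
            raise ValueError("surface carries no death counts / person-years")
        i, j, k = self._loc(country, sex, year)
        return self._deaths[i, j, k].copy(), self._py[i, j, k].copy()

    @property
    def rate_array(self) -> np.ndarray:
        """Read-only view of the dense (country, sex, year, band, cause) rate array."""
        v = self._rate.view()
        v.flags.writeable = False
        return v

    @property
    def deaths_array(self) -> np.ndarray | None:
        if self._deaths is None:
            return None
        v = self._deaths.view()
        v.flags.writeable = False
        return v

    @property
    def person_years_array(self) -> np.ndarray | None:
        if self._py is None:
            return None
        v = self._py.view()
        v.flags.writeable = False
        return v

    # -- derived surfaces --------------------------------------------

    def subset(
        self,
        countries: Iterable[str] | None = None,
        sexes: Iterable[str] | None = None,
        years: Iterable[int] | None = None,
    ) -> "MortalitySurface":
        cs = list(countries) if countries is not None else list(self.countries)
        ss = list(sexes) if sexes is not None else list(self.sexes)
        ys = [int(y) for y in years] if years is not None else list(self.years)
        ci = [self._ci[c] for c in cs]
        si = [self._si[s] for s in ss]
        yi = [self._yi[y] for y in ys]
        take = np.ix_(ci, si, yi)
        return MortalitySurface(
            self._rate[take],
            cs,
            ss,
            ys,
            self.grid,
            self.causes,
            None if self._deaths is None else self._deaths[take],
            None if self._py is None else self._py[take],
        )

    def with_rates(self, rate: np.ndarray, deaths: np.ndarray | None = None) -> "MortalitySurface":
        """Same index, replacement rate array (used for uncertainty draws)."""
        return MortalitySurface(
            rate, self.countries, self.sexes, self.years, self.grid, self.causes,
            deaths, None if deaths is None else self._py,
        )

    # -- tidy form ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long tidy frame: country, sex, year, age_start, cause, rate[, deaths, person_years]."""
        idx = pd.MultiIndex.from_product(
            [self.countries, self.sexes, self.years, self.grid.band_start, self.causes],
            names=["country", "sex", "year", "age_start", "cause"],
        )
        df = pd.DataFrame({"rate": self._rate.ravel()}, index=idx).reset_index()
        if self.has_counts:
            df["deaths"] = self._deaths.ravel()
            df["person_years"] = self._py.ravel()
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        grid: AgeGrid,
        causes: Sequence[str],
    ) -> "MortalitySurface":
        """Build from a long frame, enforcing index completeness.

        The frame must carry columns country, sex, year, age_start,
        cause and either rate or deaths + person_years.  Every
        (country, sex, year) block must contain all bands and all
        causes; missing cells are a hard error (explicit zeros are
        required, silent imputation would mask data problems).
        """
        required = {"country", "sex", "year", "age_start", "cause"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"input frame lacks columns: {sorted(missing_cols)}")
        has_counts = {"deaths", "person_years"} <= set(df.columns)
        if "rate" not in df.columns and not has_counts:
            raise ValueError("input frame must carry 'rate' or 'deaths' + 'person_years'")

        countries = sorted(df["country"].unique())
        sexes = [s for s in SEXES if s in set(df["sex"])] or sorted(df["sex"].unique())
        years = sorted(int(y) for y in df["year"].unique())
        causes = list(causes)

        full = pd.MultiIndex.from_product(
            [countries, sexes, years, grid.band_start, causes],
            names=["country", "sex", "year", "age_start", "cause"],
        )
        work = df.copy()
        work["age_start"] = work["age_start"].astype(float)
        work["year"] = work["year"].astype(int)
        dupes = work.duplicated(subset=["country", "sex", "year", "age_start", "cause"])
        if dupes.any():
            raise ValueError(f"{int(dupes.sum())} duplicate (country, sex, year, age_start, cause) rows")
        work = work.set_index(["country", "sex", "year", "age_start", "cause"])
        unknown = work.index.difference(full)
        if len(unknown):
            raise ValueError(
                "rows outside the expected grid/cause index, e.g. "
                + "; ".join(map(str, unknown[:5].tolist()))
            )
        shape = (len(countries), len(sexes), len(years), grid.n_bands, len(causes))

        def dense(col: str) -> np.ndarray:
            vals = work[col].reindex(full)
            if vals.isna().any():
                bad = vals.index[vals.isna().to_numpy()]
                head = "; ".join(map(str, bad[:10].tolist()))
                raise ValueError(
                    f"{len(bad)} missing cells (explicit zeros required), e.g. {head}"
                )
            return vals.to_numpy(dtype=float).reshape(shape)

        if has_counts:
            deaths = dense("deaths")
            py = dense("person_years")
            rate = dense("rate") if "rate" in work.columns else deaths / py
            return cls(rate, countries, sexes, years, grid, causes, deaths, py)
        return cls(dense("rate"), countries, sexes, years, grid, causes)
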