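"""Cohort-component projection of FGM incidence and prevalence.

Incidence is the probability that a girl of exact age ``a`` is cut in
year ``t`` (ages 0-14); prevalence at age ``a`` in year ``t`` is the sum
of the cohort's incidences at each earlier age, each taken from the year
in which the cohort was that age:

    prevalence[a, t] = sum_{i=0..a} incidence[i, t - (a - i)]

Women aged 15-49 are assumed not to be cut after age 14, so adult
prevalence changes only by cohort replacement:

    prevalence[a, t] = prevalence[a-1, t-1]   for a >= 15.

Pre-horizon incidence needed by the lagged sum is supplied as boundary
columns; :func:`stationary_incidence` reconstructs such a boundary from a
baseline prevalence-by-age vector under stationarity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BoundaryError, ValidationError


@dataclass
class Surface:
    """A (age x year) grid of proportions with explicit axis labels."""

    values: np.ndarray
    ages: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.shape != (len(self.ages), len(self.years)):
            raise ValidationError(
                f"surface shape {self.values.shape} does not match "
                f"{len(self.ages)} ages x {len(self.years)} years"
            )
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValidationError("surface values must lie in [0, 1]")

    def has(self, age: int, year: int) -> bool:
        return age in self.ages and year in self.years

    def at(self, age: int, year: int) -> float:
        if not self.has(age, year):
            raise BoundaryError(f"surface has no cell (age={age}, year={year})")
        ai = int(np.where(self.ages == age)[0][0])
        yi = int(np.where(self.years == year)[0][0])
        return float(self.values[ai, yi])

    def copy(self) -> "Surface":
        return type(self)(self.values.copy(), self.ages.copy(), self.years.copy())

    def to_frame(self, value_name: str = "value") -> pd.DataFrame:
        """Long-format (age, year, value) frame; the CSV interchange layout."""
        a, y = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame(
            {"age": a.ravel(), "year": y.ravel(), value_name: self.values.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_name: str = "value") -> "Surface":
        pivot = df.pivot(index="age", columns="year", values=value_name).sort_index()
        if pivot.isna().any().any():
            raise ValidationError("surface frame has missing (age, year) cells")
        return cls(pivot.to_numpy(), pivot.index.to_numpy(), pivot.columns.to_numpy())


class IncidenceSurface(Surface):
    """Incidence (probability of being cut at exact age a in year t), ages 0-14."""

    def validate_cohorts(self) -> None:
        """Check cumulative incidence over ages 0-14 within each cohort <= 1."""
        for birth_year in range(
            int(self.years.min()), int(self.years.max()) - int(self.ages.max()) + 1
        ):
            total = sum(
                self.at(a, birth_year + a) for a in self.ages
            )
            if total > 1 + 1e-9:
                raise ValidationError(
                    f"cohort born {birth_year}: cumulative incidence {total:.4f} > 1"
                )


class PrevalenceSurface(Surface):
    """Prevalence (proportion ever cut at age a in year t), ages 0-49."""


def prevalence_at(incidence: IncidenceSurface, a: int, t: int) -> float:
    """Child prevalence from the lagged incidence sum.

    Requires incidence at every (i, t-(a-i)) for i <= a; a missing boundary
    cell raises :class:`BoundaryError` naming it.
    """
    if not 0 <= a <= 14:
        raise ValidationError("a: child prevalence is defined for ages 0-14")
    total = 0.0
    for i in range(a + 1):
        total += incidence.at(i, t - (a - i))
    return total


def carry_forward_adults(prev: PrevalenceSurface, t: int) -> PrevalenceSurface:
    """Fill year ``t`` for ages >= 15 from year ``t-1`` one age younger.

    Ages below 15 are left untouched.  Returns a new surface.
    """
    if t - 1 not in prev.years:
        raise BoundaryError(f"surface has no year {t - 1} to carry forward from")
    if t not in prev.years:
        raise BoundaryError(f"surface has no year {t}")
    out = prev.copy()
    yi = int(np.where(out.years == t)[0][0])
    for a in out.ages:
        if a >= 15:
            out.values[int(np.where(out.ages == a)[0][0]), yi] = prev.at(a - 1, t - 1)
    return out


def project_prevalence(
    incidence: IncidenceSurface,
    adult_baseline: np.ndarray,
    years: range,
) -> PrevalenceSurface:
    """Full prevalence surface for ages 0-49 over ``years``.

    Child ages use the lagged incidence sum (the incidence surface must
    extend back ``max age`` years before ``years[0]``); ages 15-49 start
    from ``adult_baseline`` (prevalence at ages 15..49 in ``years[0]``) and
    are carried forward by cohort replacement, with age 15 picking up the
    age-14 child prevalence of the previous year.
    """
    adult_baseline = np.asarray(adult_baseline, dtype=float)
    if len(adult_baseline) != 35:
        raise ValidationError("adult_baseline: need prevalence for ages 15..49")
    years = list(years)
    ages = np.arange(50)
    values = np.zeros((50, len(years)))
    for yi, t in enumerate(years):
        for a in range(15):
            values[a, yi] = prevalence_at(incidence, a, t)
    values[15:, 0] = adult_baseline
    for yi, t in enumerate(years[1:], start=1):
        for a in range(15, 50):
            values[a, yi] = values[a - 1, yi - 1]
    return PrevalenceSurface(np.clip(values, 0.0, 1.0), ages, np.asarray(years))


def annual_cases(
    incidence: IncidenceSurface, population_by_age: np.ndarray
) -> pd.Series:
    """New cases per year: sum over ages of incidence x girls of that age.

    ``population_by_age`` is either a vector (constant over years) or an
    (ages x years) array matching the surface.
    """
    pop = np.asarray(population_by_age, dtype=float)
    if (pop < 0).any():
        raise ValidationError("population_by_age: negative values")
    if pop.ndim == 1:
        if len(pop) != len(incidence.ages):
            raise ValidationError(
                f"population has {len(pop)} ages, surface has {len(incidence.ages)}"
            )
        cases = incidence.values.T @ pop
    elif pop.shape == incidence.values.shape:
        cases = (incidence.values * pop).sum(axis=0)
    else:
        raise ValidationError(
            f"population shape {pop.shape} does not match surface {incidence.values.shape}"
        )
    return pd.Series(cases, index=incidence.years, name="cases")


def stationary_incidence(prevalence_by_age: np.ndarray) -> np.ndarray:
    """Age-specific incidence consistent with a stationary child prevalence profile.

    Under stationarity prevalence at age a is the running sum of incidence
    up to a, so incidence is the first difference of the profile.
    """
    prev = np.asarray(prevalence_by_age, dtype=float)
    inc = np.diff(prev, prepend=0.0)
    if (inc < -1e-9).any():
        raise ValidationError("prevalence_by_age: must be non-decreasing in age")
    return np.clip(inc, 0.0, 1.0)


def trended_incidence(
    base_hazard: np.ndarray,
    years: range,
    annual_decline: float,
    base_year: int,
) -> IncidenceSurface:
    """Incidence surface declining geometrically at the historic trend.

    ``incidence[a, t] = base_hazard[a] * (1 - annual_decline)^(t - base_year)``,
    clamped to [0, 1]; negative exponents extend the same trajectory into
    pre-horizon boundary years.
    """
    base = np.asarray(base_hazard, dtype=float)
    years_arr = np.asarray(list(years), dtype=int)
    factors = (1.0 - annual_decline) ** (years_arr - base_year).astype(float)
    values = np.clip(np.outer(base, factors), 0.0, 1.0)
    return IncidenceSurface(values, np.arange(len(base)), years_arr)
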