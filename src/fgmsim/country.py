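"""Static per-country inputs to the costing and impact pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError


@dataclass
class CountryProfile:
    """Country parameters the costing and projection stages consume.

    Populations are total persons by single year of age 0-49 (both sexes;
    the female share is taken as one half when counting girls at risk).
    ``gdp_ppp`` is per-capita GDP at purchasing power parity in
    international dollars, used only as a unit-cost transfer ratio.
    Provider, legal-personnel and first-birth counts are inputs, not
    derived quantities; they may be expected (fractional) counts.
    """

    name: str
    population_by_age: np.ndarray
    gdp_ppp: float
    legislation_present: bool
    type3_share: float
    health_providers: float
    legal_personnel: float
    first_births_per_year: float
    historic_trend: float
    n_communities: int
    region: str = ""
    conflict: bool = False

    def __post_init__(self) -> None:
        self.population_by_age = np.asarray(self.population_by_age, dtype=float)
        if self.population_by_age.ndim != 1 or len(self.population_by_age) < 15:
            raise ValidationError("population_by_age: need single ages 0..>=14")
        if (self.population_by_age < 0).any():
            raise ValidationError("population_by_age: negative values")
        if self.gdp_ppp <= 0:
            raise ValidationError("gdp_ppp: must be positive")
        if not 0 <= self.type3_share <= 1:
            raise ValidationError("type3_share: must lie in [0, 1]")
        if not 0 <= self.historic_trend < 1:
            raise ValidationError("historic_trend: must lie in [0, 1)")
        if self.n_communities < 1:
            raise ValidationError("n_communities: must be >= 1")

    @property
    def total_population(self) -> float:
        return float(self.population_by_age.sum())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["population_by_age"] = [float(x) for x in self.population_by_age]
        for k, v in d.items():
            if isinstance(v, np.floating):
                d[k] = float(v)
            elif isinstance(v, (np.integer, np.bool_)):
                d[k] = v.item()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CountryProfile":
        return cls(**d)
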