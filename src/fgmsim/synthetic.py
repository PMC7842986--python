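"""Synthetic DHS/MICS-like microdata and country parameter sets.

Real individual-recode survey extracts cannot be redistributed, so every
downstream stage of the pipeline is exercised on generated data that has
the statistical structure the analysis assumes: women clustered in
communities, community-level approval of FGM drawn from a configurable
mixture, individual support Bernoulli around the community mean, and
daughter-cut outcomes simulated from a known logistic model so that
parameter recovery can be checked end to end.

The generator does not emulate DHS sampling weights, stratification or
nonresponse.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .country import CountryProfile
from .errors import ValidationError
from .norms import CutProbabilityModel

#: religion categories and sampling probabilities used by the generator
DEFAULT_RELIGION_PROBS: dict[str, float] = {
    "muslim": 0.6,
    "christian": 0.3,
    "traditional": 0.1,
}


def default_cut_coefficients() -> CutProbabilityModel:
    """Plausible generating coefficients for the daughter-cut model.

    Positive weights on the mother's own support and on average community
    support (the two levers the interventions act on), mild protective
    gradients for wealth, education and urban residence.
    """
    return CutProbabilityModel(
        intercept=-2.2,
        coef_individual_support=1.5,
        coef_community_support=2.0,
        coef_controls={
            "age": 0.01,
            "wealth": -0.08,
            "education": -0.15,
            "urban": -0.20,
            "religion:christian": -0.30,
            "religion:traditional": 0.20,
        },
        religion_reference="muslim",
    )


@dataclass
class SyntheticCountrySpec:
    """Parameters of one synthetic country.

    ``approval_mixture`` is a list of ``(share_of_communities,
    mean_support_probability)`` pairs; shares must sum to 1.  Communities
    average 600 persons; ``women_per_community`` is the survey take per
    cluster (defaults to ``community_size``).  ``historic_trend`` is the
    annual proportional decline in community approval.
    """

    n_communities: int = 80
    community_size: int = 600
    approval_mixture: Sequence[tuple[float, float]] = (
        (0.55, 0.85),
        (0.25, 0.45),
        (0.20, 0.12),
    )
    covariate_model: Mapping[str, float] | None = None
    true_cut_coefficients: CutProbabilityModel = field(
        default_factory=default_cut_coefficients
    )
    historic_trend: float = 0.02
    base_population_by_age: np.ndarray | None = None
    total_population: float = 6_000_000.0
    gdp_ppp: float = 5_000.0
    legislation_present: bool = True
    type3_share: float = 0.10
    seed: int = 0
    women_per_community: int | None = None

    def validate(self) -> None:
        if self.n_communities < 1:
            raise ValidationError("n_communities: must be >= 1")
        if self.community_size < 1:
            raise ValidationError("community_size: must be >= 1")
        shares = np.array([s for s, _ in self.approval_mixture], dtype=float)
        means = np.array([m for _, m in self.approval_mixture], dtype=float)
        if len(shares) == 0 or not np.isclose(shares.sum(), 1.0, atol=1e-9):
            raise ValidationError(
                f"approval_mixture: component shares must sum to 1, got {shares.sum():.6f}"
            )
        if (shares < 0).any():
            raise ValidationError("approval_mixture: shares must be nonnegative")
        if ((means < 0) | (means > 1)).any():
            raise ValidationError("approval_mixture: support means must lie in [0, 1]")
        if not 0 <= self.historic_trend < 1:
            raise ValidationError("historic_trend: must lie in [0, 1)")
        if not 0 <= self.type3_share <= 1:
            raise ValidationError("type3_share: must lie in [0, 1]")


def _sample_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    religions = list(DEFAULT_RELIGION_PROBS)
    probs = list(DEFAULT_RELIGION_PROBS.values())
    return pd.DataFrame(
        {
            "age": rng.integers(15, 50, n),
            "wealth": rng.integers(1, 6, n),
            "education": rng.integers(0, 4, n),
            "urban": (rng.random(n) < 0.35).astype(int),
            "religion": rng.choice(religions, n, p=probs),
        }
    )


def generate_microdata(spec: SyntheticCountrySpec) -> pd.DataFrame:
    """Simulate a woman-level survey extract for one country.

    Each community is assigned an approval-mixture component; individual
    support is Bernoulli at the component mean (shifted on the logit scale
    by ``covariate_model`` when given); the daughter-cut indicator is
    Bernoulli from ``true_cut_coefficients`` evaluated at the woman's
    support, the empirical community mean support, and her covariates.
    Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shares = np.array([s for s, _ in spec.approval_mixture], dtype=float)
    means = np.array([m for _, m in spec.approval_mixture], dtype=float)
    component = rng.choice(len(shares), size=spec.n_communities, p=shares / shares.sum())
    community_p = means[component]
    take = spec.women_per_community or spec.community_size

    frames = []
    for c in range(spec.n_communities):
        cov = _sample_covariates(rng, take)
        p = community_p[c]
        if spec.covariate_model:
            eta = logit(np.clip(p, 1e-9, 1 - 1e-9))
            for name, beta in spec.covariate_model.items():
                if name.startswith("religion:"):
                    eta = eta + beta * (cov["religion"] == name.split(":", 1)[1]).to_numpy(float)
                elif name in cov:
                    eta = eta + beta * cov[name].to_numpy(float)
                else:
                    raise ValidationError(f"covariate_model: unknown covariate {name!r}")
            p_i = expit(eta)
        else:
            p_i = np.full(take, p)
        cov.insert(0, "community_id", c)
        cov["supports_fgm"] = (rng.random(take) < p_i).astype(int)
        frames.append(cov)
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "woman_id", np.arange(len(df)))

    comm_mean = df.groupby("community_id")["supports_fgm"].transform("mean")
    eta = spec.true_cut_coefficients.linear_predictor(
        df["supports_fgm"].to_numpy(float), comm_mean.to_numpy(float), df
    )
    df["daughter_cut"] = (rng.random(len(df)) < expit(eta)).astype(int)
    return df


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


def generate_country_profile(
    spec: SyntheticCountrySpec,
    years: range,
    *,
    name: str = "synthetic",
    region: str = "",
    conflict: bool = False,
) -> CountryProfile:
    """Build the static country inputs matching a synthetic spec.

    The age pyramid defaults to a gentle geometric decline over ages 0-49
    normalized to ``total_population``.  Provider and legal-personnel
    counts use fixed per-capita densities (1.5 and 0.2 per 1,000 persons);
    first births per year are approximated as the female population at age
    20.  The national community count is total population divided by the
    average community size, rounded half up.
    """
    spec.validate()
    if len(years) == 0:
        raise ValidationError("years: must be nonempty")
    if spec.base_population_by_age is not None:
        pop = np.asarray(spec.base_population_by_age, dtype=float)
    else:
        weights = (1 - 0.018) ** np.arange(50)
        pop = spec.total_population * weights / weights.sum()
    total = float(pop.sum())
    return CountryProfile(
        name=name,
        population_by_age=pop,
        gdp_ppp=spec.gdp_ppp,
        legislation_present=spec.legislation_present,
        type3_share=spec.type3_share,
        health_providers=total * 1.5e-3,
        legal_personnel=total * 2.0e-4,
        first_births_per_year=0.5 * pop[min(20, len(pop) - 1)],
        historic_trend=spec.historic_trend,
        n_communities=round_half_up(total / spec.community_size),
        region=region,
        conflict=conflict,
    )


def evolve_approval(
    community_support: np.ndarray | float, historic_trend: float, n_years: int
) -> np.ndarray | float:
    """Geometric decline of community approval over ``n_years``.

    Each community's support is multiplied by ``(1 - trend) ** n_years``
    and clamped to [0, 1].
    """
    if n_years < 0:
        raise ValidationError("n_years: must be nonnegative")
    if not 0 <= historic_trend < 1:
        raise ValidationError("historic_trend: must lie in [0, 1)")
    support = np.asarray(community_support, dtype=float)
    if ((support < 0) | (support > 1)).any():
        raise ValidationError("community_support: values must lie in [0, 1]")
    out = np.clip(support * (1.0 - historic_trend) ** n_years, 0.0, 1.0)
    return float(out) if np.isscalar(community_support) else out


# ---------------------------------------------------------------------------
# multi-country synthetic sets
# ---------------------------------------------------------------------------

_REGIONS = ("Asia", "Middle East and North Africa", "Sub-Saharan Africa")


def synthetic_country_set(
    n_countries: int,
    seed: int,
    *,
    n_communities: int = 60,
    women_per_community: int = 150,
) -> list[tuple[str, SyntheticCountrySpec, CountryProfile, pd.DataFrame]]:
    """Generate a varied set of synthetic countries for scenario runs.

    Populations, GDP, approval mixtures, historic trends, legislation
    status and infibulation share vary randomly across countries; regions
    rotate and every fourth country is in conflict, so any set of two or
    more countries contains both conflict and non-conflict members.
    Returns ``(name, spec, profile, microdata)`` tuples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_countries):
        high = rng.uniform(0.55, 0.95)
        mid = rng.uniform(0.30, 0.50)
        low = rng.uniform(0.02, 0.25)
        w_high = rng.uniform(0.25, 0.70)
        w_mid = rng.uniform(0.10, min(0.9 - w_high, 0.4))
        mixture = (
            (w_high, high),
            (w_mid, mid),
            (1.0 - w_high - w_mid, low),
        )
        spec = SyntheticCountrySpec(
            n_communities=n_communities,
            community_size=600,
            women_per_community=women_per_community,
            approval_mixture=mixture,
            historic_trend=float(rng.uniform(0.0, 0.06)),
            total_population=float(rng.uniform(1e6, 5e7)),
            gdp_ppp=float(rng.uniform(1_500, 12_000)),
            legislation_present=bool(rng.random() < 0.74),
            type3_share=float(rng.uniform(0.01, 0.40)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        name = f"country_{i:02d}"
        profile = generate_country_profile(
            spec,
            range(2020, 2031),
            name=name,
            region=_REGIONS[i % len(_REGIONS)],
            conflict=(i % 4 == 1),
        )
        out.append((name, spec, profile, generate_microdata(spec)))
    return out
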