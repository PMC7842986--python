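"""National intervention costing.

For each intervention and year:

    target population x PIN x coverage = number reached
    number reached x unit cost        = activity (service) cost

PIN (population in need) is the share of the target population that
should receive the service — for community-based interventions the share
of communities where more than 50% of members approve of FGM, a pool
that shrinks over time with the historic approval trend.  Unit costs are
transferred between countries by the ratio of per-capita GDP (PPP).
Program support is added as percentage markups over service delivery
(program HR 1%, supervision 2%, transport 2%, communications 1%, M&E
7.5%, management 12%, plus 1% safety in conflict countries).  All money
is constant 2020 USD with no inflation or discounting.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .country import CountryProfile
from .errors import ValidationError
from .synthetic import evolve_approval

CATEGORIES = ("prevention", "protection", "care")

#: PIN rules
PIN_ELIGIBLE_COMMUNITIES = "eligible_communities"
PIN_ALL = "all"
PIN_LEGISLATION_NEEDED = "legislation_needed"
PIN_TYPE3_SHARE = "type3_share"

#: coverage rules: ramp of direct community coverage, of combined
#: (direct+indirect) coverage, or a front-loaded fixed line item
COV_DIRECT = "direct"
COV_COMBINED = "combined"
COV_FIXED = "fixed"


@dataclass(frozen=True)
class InterventionDefinition:
    """One costed intervention: its target population, PIN and unit basis."""

    name: str
    category: str
    target: str  # communities | health_providers | legal_personnel | country | first_births
    pin_rule: str
    unit_basis: str  # per community | per person | per event | per country
    coverage_rule: str = COV_COMBINED
    front_loaded: bool = False


#: the intervention menu: prevention, protection, and care & treatment
INTERVENTIONS: dict[str, InterventionDefinition] = {
    d.name: d
    for d in (
        InterventionDefinition(
            "community_empowerment", "prevention", "communities",
            PIN_ELIGIBLE_COMMUNITIES, "per community", COV_DIRECT,
        ),
        InterventionDefinition(
            "mass_media", "prevention", "communities",
            PIN_ELIGIBLE_COMMUNITIES, "per community", COV_COMBINED,
        ),
        InterventionDefinition(
            "provider_prevention_training", "prevention", "health_providers",
            PIN_ELIGIBLE_COMMUNITIES, "per person", COV_COMBINED,
        ),
        InterventionDefinition(
            "legislation_development", "protection", "country",
            PIN_LEGISLATION_NEEDED, "per country", COV_FIXED, front_loaded=True,
        ),
        InterventionDefinition(
            "mobile_courts", "protection", "communities",
            PIN_ELIGIBLE_COMMUNITIES, "per community", COV_COMBINED,
        ),
        InterventionDefinition(
            "legal_capacity_building", "protection", "legal_personnel",
            PIN_ALL, "per person", COV_COMBINED,
        ),
        InterventionDefinition(
            "psychosocial_support", "care", "first_births",
            PIN_TYPE3_SHARE, "per person", COV_COMBINED,
        ),
        InterventionDefinition(
            "provider_care_training", "care", "health_providers",
            PIN_ELIGIBLE_COMMUNITIES, "per person", COV_COMBINED,
        ),
    )
}


@dataclass(frozen=True)
class UnitCostEntry:
    """A reference unit cost and the GDP (PPP) of its country of origin."""

    intervention: str
    reference_cost: float  # 2020 USD per unit
    reference_gdp_ppp: float  # per-capita international dollars

    def __post_init__(self) -> None:
        if self.reference_cost < 0:
            raise ValidationError("reference_cost: must be nonnegative")
        if self.reference_gdp_ppp <= 0:
            raise ValidationError("reference_gdp_ppp: must be positive")


def default_unit_costs(reference_gdp_ppp: float = 5_000.0) -> dict[str, UnitCostEntry]:
    """Synthetic reference unit-cost table (2020 USD).

    Stand-in values at plausible orders of magnitude for community
    empowerment programs, media, trainings, legal work and psychosocial
    care; real program cost data should replace them via the CSV reader.
    """
    costs = {
        "community_empowerment": 2_500.0,
        "mass_media": 300.0,
        "provider_prevention_training": 150.0,
        "legislation_development": 300_000.0,
        "mobile_courts": 400.0,
        "legal_capacity_building": 200.0,
        "psychosocial_support": 60.0,
        "provider_care_training": 150.0,
    }
    return {
        name: UnitCostEntry(name, cost, reference_gdp_ppp)
        for name, cost in costs.items()
    }


@dataclass(frozen=True)
class MarkupSchedule:
    """Program support costs as percentages over service delivery."""

    program_hr: float = 1.0
    supervision: float = 2.0
    transport: float = 2.0
    communications: float = 1.0
    monitoring_evaluation: float = 7.5
    program_management: float = 12.0
    safety_conflict: float = 1.0  # conflict countries only

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name}: markup must be nonnegative")

    def total_pct(self, conflict: bool) -> float:
        base = (
            self.program_hr
            + self.supervision
            + self.transport
            + self.communications
            + self.monitoring_evaluation
            + self.program_management
        )
        return base + (self.safety_conflict if conflict else 0.0)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def transfer_unit_cost(entry: UnitCostEntry, target_gdp_ppp: float) -> float:
    """Scale a reference unit cost by the GDP (PPP) ratio of the target country."""
    if target_gdp_ppp <= 0:
        raise ValidationError("target_gdp_ppp: must be positive")
    return entry.reference_cost * (target_gdp_ppp / entry.reference_gdp_ppp)


def number_reached(target_population: float, pin: float, coverage: float) -> float:
    """Target population x PIN x coverage."""
    if not 0 <= pin <= 1:
        raise ValidationError("pin: must lie in [0, 1]")
    if not 0 <= coverage <= 1:
        raise ValidationError("coverage: must lie in [0, 1]")
    if target_population < 0:
        raise ValidationError("target_population: must be nonnegative")
    return target_population * pin * coverage


def activity_cost(n_reached: float, unit_cost: float) -> float:
    """Number reached x unit cost."""
    return n_reached * unit_cost


def apply_markups(
    service_cost: float, schedule: MarkupSchedule, conflict: bool
) -> float:
    """Total cost including program support markups."""
    if service_cost < 0:
        raise ValidationError("service_cost: must be nonnegative")
    return service_cost * (1.0 + schedule.total_pct(conflict) / 100.0)


@dataclass
class CountryYearState:
    """The country-year facts PIN rules depend on."""

    year: int
    base_year: int
    community_approvals: np.ndarray  # baseline approval per community
    historic_trend: float
    legislation_present: bool
    type3_share: float


def eligible_community_share(
    approvals: np.ndarray, trend: float, n_years: int
) -> float:
    """Share of communities still above 50% approval after trend decline."""
    evolved = evolve_approval(np.asarray(approvals, dtype=float), trend, n_years)
    return float(np.mean(evolved > 0.5))


def pin_for_year(intervention: InterventionDefinition, state: CountryYearState) -> float:
    """Population in need for one intervention in one country-year."""
    if intervention.name not in INTERVENTIONS:
        raise ValidationError(f"unknown intervention {intervention.name!r}")
    rule = intervention.pin_rule
    if rule == PIN_ELIGIBLE_COMMUNITIES:
        return eligible_community_share(
            state.community_approvals, state.historic_trend,
            max(0, state.year - state.base_year),
        )
    if rule == PIN_LEGISLATION_NEEDED:
        return 0.0 if state.legislation_present else 1.0
    if rule == PIN_ALL:
        return 1.0
    if rule == PIN_TYPE3_SHARE:
        return state.type3_share
    raise ValidationError(f"unknown PIN rule {rule!r}")


def coverage_trajectory(
    start_year: int, end_year: int, target: float, delay_years: int = 0
) -> dict[int, float]:
    """Linear coverage ramp from 0 at start (+delay) to the target at end.

    A start delay (e.g. a 2-year pandemic delay) keeps the end year fixed,
    so the ramp is steeper but the achieved per-year coverage is lower.
    """
    if not 0 <= target <= 1:
        raise ValidationError("target: must lie in [0, 1]")
    if end_year < start_year:
        raise ValidationError("end_year: must be >= start_year")
    ramp_start = start_year + delay_years
    if ramp_start >= end_year:
        raise ValidationError("delay_years: pushes the ramp start past the end year")
    out: dict[int, float] = {}
    for y in range(start_year, end_year + 1):
        if y <= ramp_start:
            out[y] = 0.0
        else:
            out[y] = target * (y - ramp_start) / (end_year - ramp_start)
    return out


def target_population(intervention: InterventionDefinition, profile: CountryProfile) -> float:
    """Size of the group that could receive the intervention."""
    t = intervention.target
    if t == "communities":
        return float(profile.n_communities)
    if t == "health_providers":
        return float(profile.health_providers)
    if t == "legal_personnel":
        return float(profile.legal_personnel)
    if t == "country":
        return 1.0
    if t == "first_births":
        return float(profile.first_births_per_year)
    raise ValidationError(f"unknown target population {t!r}")


LEDGER_COLUMNS = (
    "country", "region", "year", "intervention", "category",
    "number_reached", "service_cost", "support_cost", "total_cost",
)


def country_cost_ledger(
    profile: CountryProfile,
    community_approvals: np.ndarray,
    unit_costs: dict[str, UnitCostEntry],
    markups: MarkupSchedule,
    *,
    direct_coverage: dict[int, float],
    combined_coverage: dict[int, float],
    front_load_years: int = 2,
    historic_trend: float | None = None,
) -> pd.DataFrame:
    """Full cost ledger for one country over the costing horizon.

    Community programs costed at direct coverage; media, courts, trainings
    and care at combined coverage; fixed per-country items (legislation)
    front-loaded evenly over the first ``front_load_years`` of the horizon
    regardless of scenario.  All money constant 2020 USD.
    """
    years = sorted(combined_coverage)
    base_year = years[0]
    trend = profile.historic_trend if historic_trend is None else historic_trend
    rows = []
    for name, idef in INTERVENTIONS.items():
        if name not in unit_costs:
            raise ValidationError(f"unit_costs: missing intervention {name!r}")
        unit = transfer_unit_cost(unit_costs[name], profile.gdp_ppp)
        tp = target_population(idef, profile)
        for y in years:
            state = CountryYearState(
                year=y, base_year=base_year,
                community_approvals=community_approvals,
                historic_trend=trend,
                legislation_present=profile.legislation_present,
                type3_share=profile.type3_share,
            )
            pin = pin_for_year(idef, state)
            if idef.coverage_rule == COV_FIXED:
                cov = 1.0 / front_load_years if y < base_year + front_load_years else 0.0
            elif idef.coverage_rule == COV_DIRECT:
                cov = direct_coverage[y]
            else:
                cov = combined_coverage[y]
            n = number_reached(tp, pin, cov)
            service = activity_cost(n, unit)
            total = apply_markups(service, markups, profile.conflict)
            rows.append(
                (profile.name, profile.region, y, name, idef.category,
                 n, service, total - service, total)
            )
    return pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))


def aggregate(ledger: pd.DataFrame, by: str | list[str]) -> pd.DataFrame:
    """Sum the ledger's money and reach columns over a grouping key.

    Totals are conserved: the grand total equals the sum over any complete
    partition.
    """
    if len(ledger) == 0:
        raise ValidationError("ledger: must be nonempty")
    keys = [by] if isinstance(by, str) else list(by)
    allowed = {"country", "region", "category", "year", "intervention"}
    unknown = set(keys) - allowed
    if unknown:
        raise ValidationError(f"unknown grouping key(s): {sorted(unknown)}")
    return (
        ledger.groupby(keys, as_index=False)[
            ["number_reached", "service_cost", "support_cost", "total_cost"]
        ].sum()
    )
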