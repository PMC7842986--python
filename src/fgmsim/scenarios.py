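"""End-to-end scale-up scenarios and the sensitivity suite.

The high-coverage scenario reaches 100% of communities with majority
(>50%) approval of FGM with either direct or indirect prevention
programs by 2030; the moderate scenario reaches 50%.  With three
communities sensitized indirectly per community reached directly, a
combined target of 100% translates into 25% direct coverage.  Costs are
accrued only during the intervention decade (2020-2030); impacts run
through a further generation of girls to 2050, with attitude change
assumed permanent.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .costing import (
    MarkupSchedule,
    UnitCostEntry,
    aggregate,
    country_cost_ledger,
    coverage_trajectory,
    default_unit_costs,
)
from .country import CountryProfile
from .demography import trended_incidence
from .errors import ValidationError
from .impact import (
    EffectSizes,
    ImpactResult,
    apply_impact,
    baseline_cell_probabilities,
    baseline_community_support,
    cases_averted,
    impact_fraction,
    national_probability,
)
from .norms import CutProbabilityModel, fit, validate_microdata

#: default age pattern of cutting over ages 0-14 (sums to 1); cutting is
#: concentrated in early childhood, tapering through early adolescence
DEFAULT_AGE_PATTERN = np.array(
    [0.16, 0.14, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05,
     0.04, 0.03, 0.02, 0.02, 0.01, 0.01]
)

FEMALE_SHARE = 0.5


@dataclass(frozen=True)
class ScenarioDefinition:
    """Everything that defines one scale-up scenario.

    ``coverage_target`` is the combined direct+indirect coverage of
    eligible communities to reach by the end year.  The direct coverage
    implied for planning uses ``planning_indirect_ratio`` (how many
    indirect communities each direct community is planned to sensitize);
    the realized ratio lives in ``effects`` so that sensitivity analysis
    on realized sensitization leaves the cost side untouched.
    ``persistence`` scales the impact fraction after the final
    implementation year (1 = effects continue at similar levels).
    """

    name: str
    coverage_target: float = 1.0
    effects: EffectSizes = field(default_factory=EffectSizes)
    planning_indirect_ratio: float = 3.0
    persistence: float = 1.0
    spillover: bool = False
    covid_delay_years: int = 0
    cost_start: int = 2020
    cost_end: int = 2030
    impact_end: int = 2050
    markups: MarkupSchedule = field(default_factory=MarkupSchedule)
    historic_trend_override: float | None = None
    front_load_years: int = 2
    age_pattern: np.ndarray = field(default_factory=lambda: DEFAULT_AGE_PATTERN.copy())

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_target <= 1:
            raise ValidationError("coverage_target: must lie in [0, 1]")
        if not 0 <= self.persistence <= 1:
            raise ValidationError("persistence: must lie in [0, 1]")

    @property
    def direct_coverage_target(self) -> float:
        return self.coverage_target / (1.0 + self.planning_indirect_ratio)


def high_coverage() -> ScenarioDefinition:
    """100% of majority-approval communities reached by 2030."""
    return ScenarioDefinition("high", coverage_target=1.0)


def moderate_coverage() -> ScenarioDefinition:
    """50% of majority-approval communities reached by 2030."""
    return ScenarioDefinition("moderate", coverage_target=0.5)


@dataclass
class CountryInputs:
    """One country's inputs to a scenario run."""

    name: str
    profile: CountryProfile
    microdata: pd.DataFrame
    model: CutProbabilityModel | None = None
    data_poor: bool = False

    def validate(self) -> None:
        try:
            validate_microdata(self.microdata)
        except ValidationError as exc:
            raise ValidationError(f"country {self.name!r}: {exc}") from exc


@dataclass
class CountryResult:
    name: str
    region: str
    p_original: float
    p_new_final: float
    eligible_share: float
    cost_total: float
    impact: ImpactResult
    ledger: pd.DataFrame


@dataclass
class ScenarioResult:
    """Aggregate costs and cases averted for one scenario."""

    name: str
    ledger: pd.DataFrame
    countries: pd.DataFrame
    total_cost: float
    cases_averted_2020_2030: float
    cases_averted_2031_2050: float
    country_results: list[CountryResult] = field(repr=False, default_factory=list)

    @property
    def cases_averted_total(self) -> float:
        return self.cases_averted_2020_2030 + self.cases_averted_2031_2050

    @property
    def cost_per_case(self) -> float:
        return cost_per_case_averted(self.total_cost, self.cases_averted_total)

    def cost_shares(self, by: str = "category") -> pd.Series:
        """Shares of the total cost; program support broken out separately.

        For ``by="category"`` service costs split into prevention /
        protection / care and all markups pool into ``program_support``;
        for ``by="region"`` total costs split by region.  Shares sum to 1.
        """
        if by == "category":
            service = self.ledger.groupby("category")["service_cost"].sum()
            service.loc["program_support"] = self.ledger["support_cost"].sum()
            return service / service.sum()
        if by == "region":
            total = self.ledger.groupby("region")["total_cost"].sum()
            return total / total.sum()
        raise ValidationError(f"unknown share key {by!r}")


def cost_per_case_averted(cost: float, averted: float) -> float:
    """Average 2020 USD spent per case of FGM averted."""
    if averted <= 0:
        raise ValidationError("averted: must be positive")
    return cost / averted


def fit_models(countries: Sequence[CountryInputs]) -> list[CountryInputs]:
    """Attach fitted cut-probability models where absent (in place, returned)."""
    for c in countries:
        if c.model is None:
            c.model = fit(c.microdata)
    return list(countries)


# ---------------------------------------------------------------------------
# per-country scenario arithmetic
# ---------------------------------------------------------------------------

def _country_scenario(
    inputs: CountryInputs,
    definition: ScenarioDefinition,
    unit_costs: dict[str, UnitCostEntry],
) -> CountryResult:
    profile = inputs.profile
    model = inputs.model
    if model is None:
        raise ValidationError(f"country {inputs.name!r}: model not fitted")
    effects = definition.effects
    trend = (
        profile.historic_trend
        if definition.historic_trend_override is None
        else definition.historic_trend_override
    )

    base_comm = baseline_community_support(inputs.microdata)
    eligible_share = float((base_comm > 0.5).mean())
    cells = baseline_cell_probabilities(
        model, inputs.microdata, effects, spillover=definition.spillover
    )
    p_original = national_probability(cells, 0.0, effects, eligible_share)

    direct_traj = coverage_trajectory(
        definition.cost_start,
        definition.cost_end,
        definition.direct_coverage_target,
        definition.covid_delay_years,
    )
    combined_traj = {
        y: min(1.0, dc * (1.0 + definition.planning_indirect_ratio))
        for y, dc in direct_traj.items()
    }

    # impact-fraction trajectory: phase-in follows the coverage ramp during
    # implementation, then persists (scaled) through the second generation
    multipliers: dict[int, float] = {}
    p_new_final = p_original
    last_if = 0.0
    for y in range(definition.cost_start, definition.impact_end + 1):
        if y <= definition.cost_end:
            dc = direct_traj[y]
            realized_combined = dc + min(1.0 - dc, effects.indirect_ratio * dc)
            p_new = national_probability(
                cells, dc, effects, eligible_share,
                spillover_coverage=realized_combined if definition.spillover else 0.0,
            )
            frac = impact_fraction(p_original, p_new) if p_original > 0 else 0.0
            last_if = frac
            p_new_final = p_new
        else:
            frac = last_if * definition.persistence
        multipliers[y] = 1.0 - frac

    base_hazard = p_original * definition.age_pattern
    horizon = range(definition.cost_start - 14, definition.impact_end + 1)
    counterfactual = trended_incidence(
        base_hazard, horizon, trend, definition.cost_start
    )
    scenario_surface = apply_impact(counterfactual, multipliers)
    girls = FEMALE_SHARE * profile.population_by_age[:15]
    impact = cases_averted(
        counterfactual,
        scenario_surface,
        girls,
        first_window=(definition.cost_start, definition.cost_end),
        second_window=(definition.cost_end + 1, definition.impact_end),
        p_original=p_original,
        p_new=p_new_final,
    )

    ledger = country_cost_ledger(
        profile,
        base_comm.to_numpy(),
        unit_costs,
        definition.markups,
        direct_coverage=direct_traj,
        combined_coverage=combined_traj,
        front_load_years=definition.front_load_years,
        historic_trend=trend,
    )
    return CountryResult(
        name=inputs.name,
        region=profile.region,
        p_original=p_original,
        p_new_final=p_new_final,
        eligible_share=eligible_share,
        cost_total=float(ledger["total_cost"].sum()),
        impact=impact,
        ledger=ledger,
    )


def run_scenario(
    countries: Sequence[CountryInputs],
    definition: ScenarioDefinition,
    unit_costs: dict[str, UnitCostEntry] | None = None,
) -> ScenarioResult:
    """Run costing and impact for every country and aggregate.

    Deterministic given the inputs (expectation-mode attitude shifts and a
    maximum-likelihood fit have no sampling step).  Any country failing
    validation aborts the run with an error naming it.
    """
    if unit_costs is None:
        unit_costs = default_unit_costs()
    for c in countries:
        c.validate()
    fit_models(countries)
    results = [_country_scenario(c, definition, unit_costs) for c in countries]
    ledger = pd.concat([r.ledger for r in results], ignore_index=True)
    country_frame = pd.DataFrame(
        {
            "country": [r.name for r in results],
            "region": [r.region for r in results],
            "eligible_share": [r.eligible_share for r in results],
            "p_original": [r.p_original for r in results],
            "p_new_final": [r.p_new_final for r in results],
            "cost_total": [r.cost_total for r in results],
            "averted_2020_2030": [r.impact.averted_2020_2030 for r in results],
            "averted_2031_2050": [r.impact.averted_2031_2050 for r in results],
        }
    )
    return ScenarioResult(
        name=definition.name,
        ledger=ledger,
        countries=country_frame,
        total_cost=float(ledger["total_cost"].sum()),
        cases_averted_2020_2030=float(country_frame["averted_2020_2030"].sum()),
        cases_averted_2031_2050=float(country_frame["averted_2031_2050"].sum()),
        country_results=results,
    )


def annual_resource_gap(
    total_cost: float, n_years: int, current_annual_spending: float
) -> float:
    """Required annual spending minus current annual spending (2020 USD)."""
    if n_years <= 0:
        raise ValidationError("n_years: must be positive")
    return total_cost / n_years - current_annual_spending


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------

def _alter(definition: ScenarioDefinition, **kw) -> ScenarioDefinition:
    return dataclasses.replace(definition, **kw)


SENSITIVITY_ROWS: dict[str, Callable[[ScenarioDefinition], ScenarioDefinition]] = {
    # realized sensitization ratio drops to 2 (planning, hence costs, unchanged)
    "indirect_ratio_2": lambda d: _alter(
        d, effects=dataclasses.replace(d.effects, indirect_ratio=2.0)
    ),
    # diffusion modeled in communities with already-negative views
    "spillover_all_communities": lambda d: _alter(d, spillover=True),
    # post-2030 effects at half strength / switched off
    "persistence_50": lambda d: _alter(d, persistence=0.5),
    "persistence_0": lambda d: _alter(d, persistence=0.0),
    # conflict-area safety at 50% of implementation costs instead of 1%
    "conflict_markup_50": lambda d: _alter(
        d, markups=dataclasses.replace(d.markups, safety_conflict=50.0)
    ),
    # no historic decline in community approval
    "zero_historic_trend": lambda d: _alter(d, historic_trend_override=0.0),
    # 2-year pandemic delay to the coverage ramp
    "covid_delay_2y": lambda d: _alter(d, covid_delay_years=2),
    # restrict to countries with usable survey data
    "drop_data_poor_countries": lambda d: d,
}


def sensitivity_suite(
    countries: Sequence[CountryInputs],
    base: ScenarioDefinition,
    rows: Sequence[str] | None = None,
    unit_costs: dict[str, UnitCostEntry] | None = None,
) -> pd.DataFrame:
    """Re-run the scenario under each alternative assumption.

    Returns one row per alternative plus the base, with total cost, cases
    averted, and percentage changes against the base run.
    """
    rows = list(rows) if rows is not None else list(SENSITIVITY_ROWS)
    unknown = [r for r in rows if r not in SENSITIVITY_ROWS]
    if unknown:
        raise ValidationError(f"unknown sensitivity row(s): {unknown}")
    fit_models(countries)

    records = []

    def record(label: str, res: ScenarioResult) -> None:
        records.append(
            {
                "row": label,
                "total_cost": res.total_cost,
                "cases_averted_2020_2030": res.cases_averted_2020_2030,
                "cases_averted_2031_2050": res.cases_averted_2031_2050,
                "cases_averted_total": res.cases_averted_total,
            }
        )

    base_res = run_scenario(countries, base, unit_costs)
    record("base", base_res)
    for name in rows:
        subset = countries
        if name == "drop_data_poor_countries":
            subset = [c for c in countries if not c.data_poor]
            if not subset:
                raise ValidationError("drop_data_poor_countries: no countries left")
        record(name, run_scenario(subset, SENSITIVITY_ROWS[name](base), unit_costs))

    out = pd.DataFrame.from_records(records)
    base_cost = out.loc[out["row"] == "base", "total_cost"].iloc[0]
    base_cases = out.loc[out["row"] == "base", "cases_averted_total"].iloc[0]
    out["pct_change_cost"] = 100.0 * (out["total_cost"] / base_cost - 1.0)
    out["pct_change_cases"] = 100.0 * (out["cases_averted_total"] / base_cases - 1.0)
    return out


# ---------------------------------------------------------------------------
# synthetic study sets
# ---------------------------------------------------------------------------

def synthetic_scenario_inputs(
    n_countries: int,
    seed: int,
    *,
    n_communities: int = 60,
    women_per_community: int = 150,
    data_poor_share: float = 9 / 31,
) -> list[CountryInputs]:
    """A varied synthetic country set wrapped as scenario inputs.

    Roughly ``data_poor_share`` of countries are flagged data-poor for the
    country-restriction sensitivity row.
    """
    from .synthetic import synthetic_country_set

    rng = np.random.default_rng(seed)
    out = []
    for name, _spec, profile, md in synthetic_country_set(
        n_countries, seed, n_communities=n_communities,
        women_per_community=women_per_community,
    ):
        out.append(
            CountryInputs(
                name=name,
                profile=profile,
                microdata=md,
                data_poor=bool(rng.random() < data_poor_share),
            )
        )
    return out
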