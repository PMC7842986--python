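"""Impact of community programs on the probability a daughter is cut.

The chain is: programs change supporter attitudes at a known effect size
(71.0% for directly reached communities, 44.6% for indirectly sensitized
neighbours), community-level support is recomputed from the changed
individual attitudes, the fitted logistic model gives a new cut
probability per woman, and the relative drop in the national probability
— the impact fraction — scales incidence downward in the counterfactual
projection.  Interventions are modeled only in communities where more
than half of members support continuing the practice; attitude change is
permanent (no reversion), so impacts run through a further generation of
girls even though costs stop with the intervention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .norms import CutProbabilityModel, community_support, predict_frame

#: community approval above which interventions are modeled (strict)
ELIGIBILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class EffectSizes:
    """Program effect sizes on supporter attitudes.

    ``direct``: share of supporters in directly reached communities whose
    attitude turns negative; ``indirect``: the same for indirectly
    sensitized communities; ``indirect_ratio``: communities sensitized
    indirectly per community reached directly.
    """

    direct: float = 0.710
    indirect: float = 0.446
    indirect_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.direct <= 1 or not 0 <= self.indirect <= 1:
            raise ValidationError("effect sizes must lie in [0, 1]")
        if self.indirect_ratio < 0:
            raise ValidationError("indirect_ratio: must be nonnegative")


@dataclass(frozen=True)
class ExposureCell:
    """One cell of the eligibility x exposure grid.

    ``eligible`` marks communities with support above 50%; ``exposure`` is
    one of ``direct``, ``indirect``, ``none``.  In the base configuration
    interventions are modeled only in eligible communities; the diffusion
    (spillover) cell for non-eligible communities is enabled separately.
    """

    eligible: bool
    exposure: str

    def __post_init__(self) -> None:
        if self.exposure not in ("direct", "indirect", "none"):
            raise ValidationError(f"exposure: unknown value {self.exposure!r}")


def flip_attitudes(
    women: pd.DataFrame,
    effect: float,
    *,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Turn supporter attitudes negative at the given effect size.

    Expectation mode (default) replaces each supporter's indicator with the
    fractional expected support ``1 - effect``; sampling mode flips each
    supporter independently with probability ``effect`` under ``rng``.
    Non-supporters never change, and changed opinions never revert.
    """
    if not 0 <= effect <= 1:
        raise ValidationError("effect: must lie in [0, 1]")
    out = women.copy()
    s = out["supports_fgm"].to_numpy(dtype=float)
    if mode == "expectation":
        out["supports_fgm"] = s * (1.0 - effect)
    elif mode == "sampling":
        if rng is None:
            raise ValidationError("sampling mode requires an rng")
        flips = (rng.random(len(s)) < effect) & (s > 0)
        out["supports_fgm"] = np.where(flips, 0.0, s)
    else:
        raise ValidationError(f"mode: unknown value {mode!r}")
    return out


def recompute_community_support(women: pd.DataFrame) -> pd.Series:
    """Community-level support after individual attitudes changed.

    The mean of the (possibly fractional) support indicator per community.
    """
    if "community_id" not in women.columns:
        raise ValidationError("community_id: column required")
    if len(women) == 0:
        raise ValidationError("community_id: no women present")
    means = women.groupby("community_id")["supports_fgm"].mean()
    return means.rename("community_support")


def baseline_community_support(women: pd.DataFrame) -> pd.Series:
    """Per-community baseline approval (mean of supports_fgm)."""
    return recompute_community_support(women)


def _cell_effect(cell: ExposureCell, effects: EffectSizes, spillover: bool) -> float:
    if cell.exposure == "direct":
        return effects.direct
    if cell.exposure == "indirect":
        return effects.indirect
    # "none": eligible communities are simply unreached; non-eligible
    # communities receive diffusion only under the spillover switch
    if not cell.eligible and spillover:
        return effects.indirect
    return 0.0


def cell_probability(
    model: CutProbabilityModel,
    women: pd.DataFrame,
    cell: ExposureCell,
    effects: EffectSizes,
    *,
    spillover: bool = False,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> float:
    """Mean cut probability for women in communities of one exposure cell.

    Selects the communities whose baseline approval matches the cell's
    eligibility, applies the cell's effect size to supporters, recomputes
    community support, and averages the model's predictions over the
    women.  Direct/indirect exposure of non-eligible communities is not
    modeled and raises.
    """
    if not cell.eligible and cell.exposure != "none":
        raise ValidationError(
            "interventions are modeled only in communities with >50% support"
        )
    base = baseline_community_support(women)
    eligible_ids = base.index[base > ELIGIBILITY_THRESHOLD]
    ids = eligible_ids if cell.eligible else base.index.difference(eligible_ids)
    sub = women[women["community_id"].isin(ids)]
    if len(sub) == 0:
        raise ValidationError(f"no women in cell {cell}")
    effect = _cell_effect(cell, effects, spillover)
    shifted = flip_attitudes(sub, effect, mode=mode, rng=rng)
    shifted = shifted.assign(community_support=community_support(shifted))
    return float(predict_frame(model, shifted).mean())


def baseline_cell_probabilities(
    model: CutProbabilityModel,
    women: pd.DataFrame,
    effects: EffectSizes,
    *,
    spillover: bool = False,
) -> dict[tuple[bool, str], float]:
    """All cell probabilities needed by :func:`national_probability`."""
    base = baseline_community_support(women)
    any_eligible = (base > ELIGIBILITY_THRESHOLD).any()
    any_noneligible = (base <= ELIGIBILITY_THRESHOLD).any()
    cells: dict[tuple[bool, str], float] = {}
    if any_eligible:
        for exposure in ("direct", "indirect", "none"):
            cells[(True, exposure)] = cell_probability(
                model, women, ExposureCell(True, exposure), effects
            )
    if any_noneligible:
        cells[(False, "none")] = cell_probability(
            model, women, ExposureCell(False, "none"), effects, spillover=False
        )
        if spillover:
            cells[(False, "spillover")] = cell_probability(
                model, women, ExposureCell(False, "none"), effects, spillover=True
            )
    return cells


def national_probability(
    cell_probs: Mapping[tuple[bool, str], float],
    direct_coverage: float,
    effects: EffectSizes,
    eligible_share: float,
    *,
    spillover_coverage: float = 0.0,
) -> float:
    """Coverage-weighted national probability that a daughter is cut.

    Among eligible communities the direct cell gets weight
    ``direct_coverage``, the indirect cell ``min(1 - direct_coverage,
    indirect_ratio * direct_coverage)`` and the unreached cell the
    remainder; non-eligible communities contribute their baseline (or
    spillover-shifted, weighted by ``spillover_coverage``) probability.
    """
    if not 0 <= direct_coverage <= 1:
        raise ValidationError("direct_coverage: must lie in [0, 1]")
    if not 0 <= eligible_share <= 1:
        raise ValidationError("eligible_share: must lie in [0, 1]")
    w_direct = direct_coverage
    w_indirect = min(1.0 - w_direct, effects.indirect_ratio * w_direct)
    w_none = 1.0 - w_direct - w_indirect
    if min(w_direct, w_indirect, w_none) < -1e-12:
        raise ValidationError("cell weights must be nonnegative")

    if eligible_share > 0:
        p_elig = (
            w_direct * cell_probs[(True, "direct")]
            + w_indirect * cell_probs[(True, "indirect")]
            + w_none * cell_probs[(True, "none")]
        )
    else:
        p_elig = 0.0
    if eligible_share < 1:
        p_base = cell_probs[(False, "none")]
        if spillover_coverage > 0 and (False, "spillover") in cell_probs:
            p_non = (
                (1 - spillover_coverage) * p_base
                + spillover_coverage * cell_probs[(False, "spillover")]
            )
        else:
            p_non = p_base
    else:
        p_non = 0.0
    return eligible_share * p_elig + (1.0 - eligible_share) * p_non


def impact_fraction(p_original: float, p_new: float) -> float:
    """Relative reduction in the cut probability: (p0 - p1) / p0."""
    if p_original <= 0:
        raise ValidationError("p_original: must be positive")
    return (p_original - p_new) / p_original


@dataclass
class ImpactResult:
    """Cases averted by a scenario relative to its counterfactual."""

    p_original: float | None
    p_new: float | None
    impact_fraction: float | None
    multipliers: pd.Series  # 1 - impact applied to incidence, by year
    annual: pd.DataFrame  # year, counterfactual, scenario, averted
    averted_2020_2030: float
    averted_2031_2050: float

    @property
    def averted_total(self) -> float:
        return self.averted_2020_2030 + self.averted_2031_2050


def apply_impact(counterfactual, multipliers: Mapping[int, float]):
    """Scenario incidence: counterfactual scaled by per-year multipliers.

    Years absent from ``multipliers`` keep the counterfactual value
    (multiplier 1); used for pre-intervention boundary years.
    """
    from .demography import IncidenceSurface

    out = counterfactual.copy()
    for yi, t in enumerate(out.years):
        m = multipliers.get(int(t), 1.0)
        if not 0 <= m <= 1 + 1e-12:
            raise ValidationError(f"multiplier for year {t} outside [0, 1]: {m}")
        out.values[:, yi] *= m
    return IncidenceSurface(out.values, out.ages, out.years)


def cases_averted(
    counterfactual,
    scenario,
    population_by_age: np.ndarray,
    *,
    first_window: tuple[int, int] = (2020, 2030),
    second_window: tuple[int, int] = (2031, 2050),
    p_original: float | None = None,
    p_new: float | None = None,
) -> ImpactResult:
    """Counterfactual minus scenario cases, split by accounting window.

    Both surfaces must share the same ages and years; the windows follow
    the convention that the first covers the intervention decade and the
    second the subsequent generation of girls.
    """
    from .demography import annual_cases

    if not np.array_equal(counterfactual.years, scenario.years) or not np.array_equal(
        counterfactual.ages, scenario.ages
    ):
        raise ValidationError("surfaces must share the same ages and years")
    cf = annual_cases(counterfactual, population_by_age)
    sc = annual_cases(scenario, population_by_age)
    annual = pd.DataFrame(
        {"counterfactual": cf, "scenario": sc, "averted": cf - sc}
    ).rename_axis("year")
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(cf.to_numpy() > 0, sc.to_numpy() / cf.to_numpy(), 1.0)
    w1 = annual.loc[first_window[0] : first_window[1], "averted"].sum()
    w2 = annual.loc[second_window[0] : second_window[1], "averted"].sum()
    frac = None
    if p_original is not None and p_new is not None:
        frac = impact_fraction(p_original, p_new)
    return ImpactResult(
        p_original=p_original,
        p_new=p_new,
        impact_fraction=frac,
        multipliers=pd.Series(mult, index=annual.index, name="multiplier"),
        annual=annual,
        averted_2020_2030=float(w1),
        averted_2031_2050=float(w2),
    )
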