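"""Project FGM prevalence with the cohort-component recursion.

Child prevalence is the lagged sum of age-specific incidence; adult
prevalence changes only as cohorts age (no cutting after 14).  A declining
incidence trend therefore takes decades to show up in adult prevalence.
"""
import numpy as np

import fgmsim as f

# baseline: 2020 cross-sectional risk of 40% by age 15, concentrated at
# young ages, incidence declining 3% per year (the trend also extends
# backwards, so cohorts who were children before 2020 faced higher rates)
pattern = np.array([0.16, 0.14, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05,
                    0.04, 0.03, 0.02, 0.02, 0.01, 0.01])
base_hazard = 0.40 * pattern
incidence = f.trended_incidence(base_hazard, range(2006, 2051), 0.03, 2020)
prevalence = f.project_prevalence(incidence, np.full(35, 0.45), range(2020, 2051))

print("year   prev@14  prev@25  prev@49   cases(100k girls/age)")
girls = np.full(15, 100_000.0)
cases = f.annual_cases(
    f.IncidenceSurface(
        incidence.values[:, np.isin(incidence.years, range(2020, 2051))],
        incidence.ages, np.arange(2020, 2051),
    ),
    girls,
)
for year in (2020, 2030, 2040, 2050):
    print(f"{year}   {prevalence.at(14, year):7.3f}  {prevalence.at(25, year):7.3f}"
          f"  {prevalence.at(49, year):7.3f}   {cases[year]:12,.0f}")
# prev@14 falls quickly with incidence; prev@49 only moves once the smaller
# child cohorts reach that age — the cohort carry-forward at work.
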