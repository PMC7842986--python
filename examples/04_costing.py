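"""Cost one country's scale-up: reach, service costs and support markups.

Walks the costing identities for a single country: target population x
PIN x coverage = number reached; number reached x unit cost = activity
cost; program-support markups on top (26.5% of service delivery in
conflict settings, 25.5% elsewhere).
"""
import fgmsim as f
from fgmsim.costing import country_cost_ledger, default_unit_costs

spec = f.SyntheticCountrySpec(total_population=6_000_000, seed=3,
                              legislation_present=False)
profile = f.generate_country_profile(spec, range(2020, 2031), name="demo")
md = f.generate_microdata(spec)
approvals = md.groupby("community_id")["supports_fgm"].mean().to_numpy()

# high-coverage scenario: 25% direct coverage by 2030, combined 100%
direct = f.coverage_trajectory(2020, 2030, 0.25)
combined = {y: min(1.0, 4 * v) for y, v in direct.items()}
ledger = country_cost_ledger(
    profile, approvals, default_unit_costs(), f.MarkupSchedule(),
    direct_coverage=direct, combined_coverage=combined,
)

print(f"communities: {profile.n_communities:,}  "
      f"eligible share 2020: {(approvals > 0.5).mean():.2f}")
print("\ntotal cost 2020-2030 by intervention (USD2020):")
by_int = f.aggregate(ledger, "intervention").sort_values("total_cost", ascending=False)
for _, row in by_int.iterrows():
    print(f"  {row['intervention']:30s} {row['total_cost']:15,.0f}")
total = ledger["total_cost"].sum()
support = ledger["support_cost"].sum()
print(f"\ngrand total: {total:,.0f} USD2020 "
      f"(program support {100 * support / total:.1f}% of total)")
# legislation appears because this country lacks an FGM law; it is a fixed
# cost front-loaded into 2020-2021 and identical across scenarios.
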