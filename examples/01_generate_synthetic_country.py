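"""Generate a synthetic DHS-like survey extract and country parameters.

Builds one country with 40 survey clusters, prints the community approval
structure the mixture induced and the national community count implied by
the average community size of 600 persons.
"""
import fgmsim as f

spec = f.SyntheticCountrySpec(
    n_communities=40,
    women_per_community=120,
    approval_mixture=((0.55, 0.85), (0.25, 0.45), (0.20, 0.12)),
    total_population=6_000_000,
    historic_trend=0.02,
    seed=42,
)
md = f.generate_microdata(spec)
profile = f.generate_country_profile(spec, range(2020, 2031), name="demo")

approval = md.groupby("community_id")["supports_fgm"].mean()
print(f"women surveyed:            {len(md):,}")
print(f"communities in survey:     {approval.size}")
print(f"communities >50% approval: {(approval > 0.5).sum()} "
      f"({100 * (approval > 0.5).mean():.0f}% of clusters)")
print(f"national daughter-cut rate in sample: {md['daughter_cut'].mean():.3f}")
print(f"national community count (pop/600):   {profile.n_communities:,}")
# The >50% communities are the pool the prevention programs target; the
# daughter-cut rate is what the scale-up scenarios will push down.
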