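"""Gridded range metrics: range size (km^2), centroids and diversity fields.

Range size sums spherical cell areas over each host's occupied 1-degree
cells; the diversity field is the mean number of co-occurring hosts per
occupied cell - a measure of how species-rich the assemblages containing a
focal host are.
"""
from parafauna import WorldConfig, generate_world, grids

world = generate_world(WorldConfig(n_hosts=40, n_parasites=20, seed=7, mode="sharing"))
summary = grids.range_summaries(world.pam)

print(summary.head(6).round(2))
print()
print(f"median range size: {summary['range_size_km2'].median():,.0f} km^2")
print(f"mean diversity field: {summary['diversity_field'].mean():.2f} co-occurring hosts")
print()
print("Hosts with large ranges tend to overlap more other species, so range")
print("size and diversity field are positively related:")
print(f"  corr(ln GR, DF) = {summary['range_size_km2'].apply('log').corr(summary['diversity_field']):.2f}")
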