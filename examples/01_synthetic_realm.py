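"""Generate a synthetic biogeographic realm with known planted parameters.

A realm bundles a pure-birth host phylogeny, 18 host traits, contiguous
gridded ranges, 12 correlated environmental layers and a parasite x host
incidence matrix drawn from a planted sharing model.
"""
from parafauna import WorldConfig, generate_world

world = generate_world(WorldConfig(n_hosts=60, n_parasites=30, seed=42,
                                   mode="sharing", sharing_distance="trait"))

print(f"hosts:      {world.pam.n_hosts}")
print(f"parasites:  {len(world.incidence)}")
print(f"grid cells: {world.config.grid.n_cells}")
print(f"incidence fill: {world.incidence.to_numpy().mean():.3f}")
print(f"planted sharing coefficients (a, b): {world.config.sharing_coefs}")
print()
print(world.traits.iloc[:3, :4])
print()
print("The incidence fill is the fraction of host-parasite pairs with a")
print("record; the planted (a, b) drive infestation probability as a")
print("logistic function of trait distance from each parasite's focal host.")
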