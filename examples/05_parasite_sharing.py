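"""Probability of parasite sharing as a function of between-host distance.

Each parasite on >= 6 hosts contributes a logistic regression of its
incidence cases on the normalized distance; a 200-iteration species
bootstrap pools the coefficients.  PNS is the proportion of parasites whose
slope is negative - values near 1 mean sharing consistently declines with
distance.
"""
import numpy as np

from parafauna import WorldConfig, generate_world, sharing

world = generate_world(WorldConfig(n_hosts=100, n_parasites=40, seed=21,
                                   mode="sharing", sharing_distance="trait",
                                   sharing_coefs=(2.0, -6.0)))
fit = sharing.pooled_coefficients(world.incidence, world.driving_distance,
                                  n_iter=200, seed=5)

print(f"eligible parasites (>= 6 hosts): {len(fit.per_parasite)}")
print(f"pooled intercept a = {fit.pooled_intercept:.3f}")
print(f"pooled slope     b = {fit.pooled_slope:.3f}")
print(f"PNS = {fit.pns:.2f}")
print()
for d in (0.0, 0.25, 0.5, 0.75, 1.0):
    p = sharing.sharing_probability(fit.pooled_intercept, fit.pooled_slope,
                                    np.array([d]))[0]
    print(f"  P(share | D = {d:.2f}) = {p:.3f}")
print()
print("The negative slope and high PNS show that hosts with similar traits")
print("share parasites far more often than dissimilar hosts, as planted.")
print("Note the pooled slope is attenuated relative to the planted -6: only")
print("the focal host of each parasite carries the planted signal, while the")
print("procedure treats every carrier as a potential source.")
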