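# parafauna

Macroecological analysis of ectoparasite faunas on small mammal hosts:
what makes a host species accumulate many flea or mite species, and how
does the probability that two host species *share* a parasite decay with
the distance between them — phylogenetic, trait-based, geographic or
environmental?

`parafauna` is a Python library for biostatisticians and parasite
ecologists working with host–parasite incidence compilations. It implements
the full analysis pipeline from gridded host ranges to fitted models, plus a
synthetic-data generator that plants known parameters so every stage can be
validated by parameter recovery.

## The models

**Species richness.** Parasite species richness per host (column sums of a
binary parasite × host incidence matrix) is modelled with a negative
binomial (NB2) GLM with a log link:

```
S_i ~ NB(mu_i, theta),   log mu_i = b0 + b1 ln BM_i + b2 ln GR_i + b3 ln DF_i + b4 HB_i
```

where BM is body mass (g), GR geographic range size (km², summed spherical
1°-cell areas), DF the diversity field (mean number of co-occurring host
species per occupied cell) and HB habitat breadth. All 2⁴ = 16 predictor
subsets are fitted and ranked by AIC (theta counted as an estimated
parameter); the best model is summarized by its explained deviance and
Nagelkerke pseudo-R². A Blomberg K/K* permutation test on richness runs
first as a gate: significant phylogenetic signal triggers a warning that an
uncorrected model is being fitted.

**Parasite sharing.** For every parasite recorded on ≥ 6 hosts, each
carrier host acts as a source: carrier–carrier pairs are positive cases,
and a balanced random sample of non-carriers per source provides negatives.
A logistic regression of the case response on the normalized between-host
distance D gives per-parasite coefficients; a species bootstrap (1000
random parasite sets by default, fresh negative samples each iteration)
pools them into the sharing curve

```
P(D) = 1 / (1 + exp(-(a + b D)))
```

together with PNS, the proportion of parasites with a negative slope.
Four distance matrices are built and normalized to [0, 1]: cophenetic
distances on the ultrametrized host tree (PD), Gower mixed-type trait
dissimilarity over 18 traits (TD), haversine distances between range
centroids (GD) and Euclidean distances between principal-component scores
of 12 environmental variables sampled with a 100-km buffer around each
centroid (ED).

## Worked example

```python
from parafauna import WorldConfig, generate_world, sharing

world = generate_world(WorldConfig(n_hosts=100, n_parasites=40, seed=21,
                                   mode="sharing", sharing_distance="trait",
                                   sharing_coefs=(2.0, -6.0)))
fit = sharing.pooled_coefficients(world.incidence, world.driving_distance,
                                  n_iter=200, seed=5)
print(fit.pooled_intercept, fit.pooled_slope, fit.pns)
```

prints (see `examples/05_parasite_sharing.py` for the full script):

```
eligible parasites (>= 6 hosts): 40
pooled intercept a = 0.909
pooled slope     b = -1.645
PNS = 0.95
  P(share | D = 0.00) = 0.713
  P(share | D = 1.00) = 0.324
```

The planted model makes infestation probability fall logistically with
trait distance from each parasite's focal host. The pooled fit recovers
the direction decisively — 95% of parasites get a negative slope, and the
fitted curve drops from 0.71 between identical hosts to 0.32 between
maximally dissimilar ones. The pooled slope is attenuated relative to the
planted per-focal-host slope because the procedure treats *every* carrier
as a source (see `docs/methods.md`).

Every other capability has a matching narrative script under `examples/`:
synthetic realms, range metrics, the four distance matrices, the richness
GLM with AIC selection, and the end-to-end pipeline. A thin CLI wraps the
pipeline:

```
parafauna simulate --outdir out --seed 3
parafauna analyze --config run.yaml
```

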