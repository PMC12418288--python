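# Methods

This note records the statistical procedures `parafauna` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real host–parasite compilations.

## Gridded range metrics

Host ranges live on a regular longitude/latitude grid (1° resolution by
default), indexed row-major from the northwest corner. Cell areas use the
spherical band formula `R² Δλ (sin φ_top − sin φ_bot)` with the IUGG mean
Earth radius R = 6371.0088 km; the constant is pinned so independent
oracles can match bit-for-bit. Range size is the sum of occupied-cell
areas; membership is binary at the whole-cell level with no partial-area
weighting, matching the convention of rasterizing range polygons to cells
before any computation.

The range centroid is the unweighted arithmetic mean of occupied cell
centers. Ranges spanning the antimeridian are remapped to [0°, 360°) when
their longitudinal extent is smaller in that frame, so a two-lobed Pacific
range cannot produce a centroid in Africa. Alternative midpoint definitions
(area-weighted, geodesic medians) exist; the mean of cell centers was
chosen for transparency and testability.

The diversity field of host *i* is `DF_i = mean over occupied cells c of
(S_c − 1)`, where `S_c` counts all hosts present in cell *c* — every host
in the matrix counts as a co-occurrer, whether or not it has parasite
records. Geographic distances between centroids use the haversine formula
on the same sphere.

## Distance matrices

All four between-host matrices are symmetric with zero diagonals and are
normalized by dividing by the largest off-diagonal entry, giving distances
in [0, 1]; the normalization constant is reported alongside each matrix.
Rescaling is monotone, so the logistic sharing model's slope changes scale
but never sign.

* **Phylogenetic (PD)** — cophenetic (patristic) distances on the host
  tree after (a) randomly resolving polytomies with zero-length inserted
  edges (path lengths are unchanged) and (b) ultrametrizing by extending
  each pendant branch to the maximum tip depth, which preserves topology
  and internal branch lengths.
* **Trait (TD)** — the Gower coefficient over 18 traits (12 continuous,
  range-scaled; 2 binary and 4 categorical as mismatch indicators), with
  pairwise trait deletion for missing values, equal weights by default and
  configurable weights per trait. A pair of hosts sharing no comparable
  trait is an error, not a silent zero. Constant continuous traits are
  dropped with a warning.
* **Environmental (ED)** — each host's environmental profile is the mean
  of 12 layer values over cells whose centers fall within 100 km of its
  range centroid (the nearest cell is always included, so small buffers
  degrade gracefully). Profiles are centered and scaled to unit variance
  before a PCA via eigendecomposition of the correlation matrix;
  standardization makes the distance invariant to the layers' units. The
  retained component count is either fixed per run (2–3 is typical for
  climatic layers) or chosen as the smallest count reaching a cumulative
  explained-variance threshold (default 0.75). ED is the Euclidean
  distance between retained score vectors.

## Richness model

`nb_glm_fit` maximizes the NB2 log-likelihood with a log link by
alternating IRLS for the coefficients at fixed dispersion θ with a
univariate ML update of θ given the fitted means, until the log-likelihood
changes by < 1e-8 (200 outer iterations maximum). This is the classic
`glm.nb` alternation, and the fit agrees with R's `MASS::glm.nb` to
printed precision on shared data. AIC counts θ as one estimated parameter;
AICc is available as a switch. All 16 predictor subsets are fitted and
ranked, ties broken toward fewer parameters.

Explained deviance is `100 (1 − D_model / D_null)` with the null deviance
evaluated **at the focal model's θ** (using the null model's fitted
means). NB deviances are only comparable at a common dispersion: with each
model's own θ, adding a genuinely predictive covariate can push ED below
zero, an artifact, so the common-dispersion convention (the one `glm.nb`'s
`null.deviance` slot uses) is applied. Nagelkerke's R² is the Cox–Snell
ratio `1 − exp((2/n)(ll_0 − ll_1))` rescaled by its maximum
`1 − exp((2/n) ll_0)`; likelihoods are comparable across θ, so it needs no
such adjustment.

Body mass, range size and diversity field enter on the natural-log scale;
habitat breadth is untransformed. Hosts with an empty diversity field get
`ln(DF + 1)` with a warning.

**Blomberg's K.** With V the Brownian covariance matrix implied by the
tree, the statistic is the ratio `(MSE0 / MSE)` of the ordinary to the
V-weighted mean squared error of tip values about a central value, divided
by its Brownian expectation `(tr V − n / Σ V⁻¹) / (n − 1)`. Variant `K`
centers on the GLS ancestral estimate; variant `K*` on the arithmetic tip
mean. On a star phylogeny both reduce to exactly 1 for any data. The
p-value is a permutation test over random tip-label shuffles,
`p = (1 + #{K_perm ≥ K_obs}) / (n_perm + 1)`. The implementation matches
`picante::Kcalc` / `phytools::phylosig` to printed precision on a shared
fixture. The richness pipeline runs this test first and warns — it does
not phylogenetically correct the GLM — mirroring the practice of fitting
uncorrected models once signal is ruled out.

## Sharing model

Eligibility requires ≥ 6 recorded hosts. For each eligible parasite, every
carrier host *s* is a source: each other carrier *t* contributes a
response-1 case at distance D(s, t), and a uniform without-replacement
sample of non-carriers of size `min(#carriers − 1, #non-carriers)` per
source contributes response-0 cases (balanced negatives; the sample size
rule is configurable). Cases are pooled across sources into a single
per-parasite logistic fit rather than fitted per source and averaged; the
pooled variant is better conditioned for parasites with few hosts. Case
construction is canonicalized by host label, so simultaneously permuting
hosts in the incidence and distance matrices leaves results unchanged for
a fixed seed.

The logistic fit is plain ML via Newton/IRLS with a log-likelihood
tolerance of 1e-10. Complete or quasi-complete separation (coefficients
diverging past ±50) and degenerate designs (constant D) are flagged
non-converged and excluded from pooling; no penalization is applied, so
the estimator stays plain ML.

The species bootstrap draws, per iteration, a with-replacement random set
of eligible parasites at the full pool size (a without-replacement subset
rule is available), refits every drawn parasite with fresh negative
samples, and records the iteration's mean intercept and slope; the pooled
coefficients are the means of those iteration means. PNS is the fraction
of converged per-parasite fits with slope < 0 (an exact zero counts as
non-negative). The probability curve uses the standard logistic
orientation `P(D) = 1/(1 + e^{−(a + bD)})`, in which a negative slope
gives sharing probability decreasing with distance.

## Synthetic realms

The generator exists so each stage has a parameter-recovery test; all
generators are pure functions of (config, seed), with per-stage substreams
derived from one global seed.

* **Phylogeny** — pure-birth: exponential waiting times at rate equal to
  the number of extant lineages, uniform choice of the splitting lineage,
  all tips extended to the final time, so the tree is exactly ultrametric
  and binary.
* **Traits** — 18 columns mirroring the standard mammal trait schema.
  Twelve continuous traits are Brownian motion on the tree mapped to
  positive scales (e.g. body mass `exp(4 + 1.2 z)` g spans shrews to
  marmots); habitat breadth is a small positive integer; the range-size
  column is overwritten from the generated ranges. Binary and categorical
  traits threshold independent Brownian latents, so all Gower code paths
  carry phylogenetic signal. Missingness is injectable by fraction.
* **Ranges** — grown from a random seed cell by 4-neighbour frontier
  accretion to a lognormal target size (median 25 cells, log-sd 0.75 on
  the default 20° × 20° grid), guaranteeing contiguity by construction.
* **Environment** — 12 layers mixing 3 latent fields (latitudinal and
  longitudinal gradients plus a Gaussian-smoothed random surface) with
  small independent noise, reproducing the strong collinearity of real
  climate layers that motivates the PCA step.
* **Incidence** — *richness mode*: per-host richness drawn from the NB
  model at planted coefficients (default (−3.3, −0.3, +0.4, +0.3, +0.1),
  the intercept centering mean richness near 7 parasites per host at the
  default trait/range scales), parasite identities assigned uniformly;
  *sharing mode*: each parasite receives a random focal host and infests
  every host independently with probability `expit(a + b D(focal, i))` on
  the chosen normalized distance matrix.

What the synthetic data do **not** emulate: real biogeography (range
cohesion follows accretion, not climate or history), co-phylogenetic
structure in the parasites, sampling effort heterogeneity, and spatial
autocorrelation in the incidence records. Passing recovery tests therefore
establishes the correctness of the estimators under their assumed models,
not the robustness of the analysis to those complications.

## Known estimand gap in sharing-mode recovery

The sharing generator plants its slope relative to each parasite's *focal*
host, while the sharing analysis — by design — treats every carrier as a
source. For non-focal sources the response depends on the target's
distance to the focal host, not to the source, so the fitted slope
estimates a flatter mixture quantity. On the default recovery conditions
(150 hosts, 60 parasites, a = 2, b = −6 on normalized trait distance) the
pooled slope comes out near −1.5: the sign, the PNS near 1, and the null
calibration (PNS ≈ 0.5 on randomized distances) are all recovered
decisively, but the planted magnitude is not, and cannot be, recovered by
this estimator. A direct fit on the true focal design does recover (a, b)
to within sampling error, which isolates the gap to the case-construction
estimand rather than to the optimizer.

## Problem sizes and numerical choices

Recovery experiments use 20 realms of 500 hosts for the richness model,
one realm of 150 hosts / 60 parasites with a 200-iteration bootstrap plus
50 randomized-distance seeds for the sharing model, and 50 replicates of
100-tip Brownian traits for the Blomberg calibration — sizes at which the
Monte-Carlo error of each checked quantity is several times smaller than
its acceptance band. Permutation tests use 99–199 permutations with the
add-one p-value estimator. Ties in AIC ranking break toward fewer
parameters; an all-zero distance matrix normalizes to itself with a
warning; an all-zero incidence draw is regenerated from a fresh substream.
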