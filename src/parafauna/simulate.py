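"""Synthetic "realms" with known planted parameters.

Every downstream stage — range metrics, distance matrices, the richness GLM
and the sharing model — gets a parameter-recovery test by generating data
from the very models those stages fit:

* an ultrametric pure-birth host phylogeny;
* 18 host traits (12 continuous, simulated by Brownian motion on the tree
  and mapped to positive trait scales; 2 binary; 4 categorical);
* contiguous gridded ranges grown by 4-neighbour accretion to lognormal
  target sizes;
* 12 cross-correlated environmental layers built from 3 latent spatial
  fields plus latitudinal/longitudinal gradients;
* a parasite x host incidence matrix drawn either from a planted
  negative-binomial richness model ("richness" mode) or from a planted
  logistic distance-decay sharing model ("sharing" mode).

All generators are pure functions of (config, seed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage, special

from . import grids, trees
from .distances import DistanceMatrix

CONTINUOUS_TRAITS = [
    "body_mass_g", "rel_brain_mass", "max_longevity_y", "age_first_repro_d",
    "gestation_d", "litter_size", "litters_per_year", "interbirth_d",
    "weaning_d", "generation_length_d", "habitat_breadth", "range_size_km2",
]
BINARY_TRAITS = ["hibernation", "fossoriality"]
CATEGORICAL_TRAITS = ["trophic_level", "foraging_stratum", "activity_cycle",
                      "substrate_pref"]
CATEGORY_LEVELS = {
    "trophic_level": ["herbivore", "omnivore", "insectivore"],
    "foraging_stratum": ["ground", "scansorial", "arboreal"],
    "activity_cycle": ["nocturnal", "diurnal", "cathemeral"],
    "substrate_pref": ["mesic", "xeric", "generalist"],
}


@dataclass(frozen=True)
class WorldConfig:
    """Configuration and planted truth for one synthetic realm."""

    n_hosts: int = 60
    n_parasites: int = 30
    grid: grids.GridSpec = field(default_factory=lambda: grids.GridSpec(0, 20, 20, 40, 1.0))
    seed: int = 0
    mode: str = "richness"  # richness | sharing
    # richness mode: log-mean coefficients (beta0, b_BM, b_GR, b_DF, b_HB);
    # beta0 centers mean richness near ~7 parasites per host at the default
    # trait/range scales
    richness_betas: tuple[float, ...] = (-3.3, -0.3, 0.4, 0.3, 0.1)
    nb_theta: float = 2.0
    # sharing mode: planted logistic intercept/slope and the driving distance
    sharing_coefs: tuple[float, float] = (2.0, -6.0)
    sharing_distance: str = "trait"  # phylo | trait | geo | env
    # range generator: lognormal target size (cells)
    range_median_cells: float = 25.0
    range_sigma: float = 0.75
    trait_missing_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_hosts < 10:
            raise ValueError("n_hosts must be >= 10")
        if self.n_parasites < 1:
            raise ValueError("n_parasites must be >= 1")
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be > 0")
        if self.mode not in ("richness", "sharing"):
            raise ValueError("mode must be 'richness' or 'sharing'")
        if self.sharing_distance not in ("phylo", "trait", "geo", "env"):
            raise ValueError("unknown sharing_distance")
        if len(self.richness_betas) != 5:
            raise ValueError("richness_betas must have 5 entries")


def _host_labels(n: int) -> list[str]:
    return [f"h{i:04d}" for i in range(n)]


def generate_phylogeny(n_hosts: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric binary tree with ``n_hosts`` tips.

    Lineages split at exponential waiting times (rate = number of extant
    lineages); at the end every pendant branch is extended to the present,
    so all root-to-tip depths are equal.
    """
    if n_hosts < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # start from the root split: two lineages at time 0
    tips = list(tree.seed_node.new_child() for _ in range(2))
    birth_times = {id(t): 0.0 for t in tips}
    t_now = 0.0
    while len(tips) < n_hosts:
        t_now += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        parent.edge.length = t_now - birth_times[id(parent)]
        children = [parent.new_child() for _ in range(2)]
        for c in children:
            birth_times[id(c)] = t_now
        tips.extend(children)
    t_end = t_now + rng.exponential(1.0 / len(tips))
    labels = _host_labels(n_hosts)
    order = rng.permutation(n_hosts)  # decouple label order from branching order
    for tip, lab_idx in zip(tips, order):
        tip.edge.length = t_end - birth_times[id(tip)]
        tip.taxon = taxa.require_taxon(label=labels[lab_idx])
    return tree


def _brownian_traits(tree, n_traits: int, rng: np.random.Generator) -> pd.DataFrame:
    """Standardized Brownian-motion trait values at the tips (one column per
    trait), simulated from the phylogenetic covariance matrix."""
    vcv = trees.phylo_vcv(tree)
    depth = float(np.diag(vcv).max())
    chol = np.linalg.cholesky(vcv.to_numpy() / depth + 1e-10 * np.eye(len(vcv)))
    z = chol @ rng.standard_normal((len(vcv), n_traits))
    return pd.DataFrame(z, index=vcv.index, columns=[f"bm{i}" for i in range(n_traits)])


def generate_traits(tree, seed: int = 0, missing_frac: float = 0.0) -> pd.DataFrame:
    """18-trait host table mirroring the standard mammal trait schema.

    Twelve continuous traits come from Brownian motion on the tree mapped to
    positive scales (body mass in grams spans shrew-to-marmot sizes; habitat
    breadth is a small positive integer; range_size_km2 is a placeholder that
    pipelines overwrite from the generated ranges), two binary and four
    three-level categorical traits from thresholded Brownian latents.
    """
    rng = np.random.default_rng(seed)
    latent = _brownian_traits(tree, 18, rng)
    hosts = latent.index
    out = pd.DataFrame(index=hosts)
    scalers = {
        "body_mass_g": lambda z: np.exp(4.0 + 1.2 * z),
        "rel_brain_mass": lambda z: np.exp(-4.0 + 0.3 * z),
        "max_longevity_y": lambda z: np.exp(1.2 + 0.4 * z),
        "age_first_repro_d": lambda z: np.exp(4.5 + 0.5 * z),
        "gestation_d": lambda z: np.exp(3.2 + 0.3 * z),
        "litter_size": lambda z: 1.0 + np.minimum(np.exp(1.0 + 0.4 * z), 11.0),
        "litters_per_year": lambda z: np.exp(0.5 + 0.4 * z),
        "interbirth_d": lambda z: np.exp(5.0 + 0.5 * z),
        "weaning_d": lambda z: np.exp(3.4 + 0.4 * z),
        "generation_length_d": lambda z: np.exp(6.5 + 0.4 * z),
        "habitat_breadth": lambda z: 1.0 + np.floor(
            4.0 * special.expit(1.2 * z + 0.3 * rng.standard_normal(len(z))) * 1.999),
        "range_size_km2": lambda z: np.exp(12.0 + 1.0 * z),
    }
    for name, zcol in zip(CONTINUOUS_TRAITS, latent.columns[:12]):
        out[name] = scalers[name](latent[zcol].to_numpy())
    for name, zcol in zip(BINARY_TRAITS, latent.columns[12:14]):
        out[name] = (latent[zcol] > 0).astype(int)
    for name, zcol in zip(CATEGORICAL_TRAITS, latent.columns[14:18]):
        z = latent[zcol]
        codes = np.digitize(z, np.quantile(z, [1 / 3, 2 / 3]))
        out[name] = [CATEGORY_LEVELS[name][c] for c in codes]
    if missing_frac > 0:
        mask = rng.random(out.shape) < missing_frac
        out = out.mask(mask)
    out.index.name = "host_id"
    return out


def generate_ranges(grid: grids.GridSpec, n_hosts: int, seed: int = 0,
                    median_cells: float = 25.0, sigma: float = 0.75,
                    ) -> grids.PresenceAbsenceMatrix:
    """Contiguous host ranges grown by random 4-neighbour accretion.

    Each host starts from a random seed cell and grows to a target size
    drawn from a lognormal distribution (given median and log-sd), truncated
    to the grid; every occupied cell stays reachable from the seed cell via
    4-neighbour steps by construction.
    """
    if grid.n_cells < 25:
        raise ValueError("grid must have at least 25 cells")
    rng = np.random.default_rng(seed)
    nr, nc = grid.n_rows, grid.n_cols
    values = np.zeros((n_hosts, grid.n_cells), dtype=np.int8)
    targets = np.round(np.exp(np.log(median_cells) + sigma * rng.standard_normal(n_hosts)))
    if (targets > grid.n_cells).any():
        warnings.warn("some target range sizes exceed the grid; truncated")
    targets = np.clip(targets, 1, grid.n_cells).astype(int)
    for h in range(n_hosts):
        start = (int(rng.integers(nr)), int(rng.integers(nc)))
        occupied = {start}
        frontier = {start}
        while len(occupied) < targets[h]:
            candidates = set()
            for (i, j) in frontier:
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    cell = (i + di, j + dj)
                    if 0 <= cell[0] < nr and 0 <= cell[1] < nc and cell not in occupied:
                        candidates.add(cell)
            if not candidates:
                break
            cand = sorted(candidates)
            n_new = min(len(cand), targets[h] - len(occupied))
            picks = rng.choice(len(cand), size=n_new, replace=False)
            new_cells = {cand[k] for k in picks}
            occupied |= new_cells
            frontier = new_cells
        for (i, j) in occupied:
            values[h, i * nc + j] = 1
    return grids.PresenceAbsenceMatrix(_host_labels(n_hosts), grid, values)


def generate_environment(grid: grids.GridSpec, seed: int = 0,
                         n_layers: int = 12, n_latent: int = 3,
                         gradient_weight: float = 1.0) -> pd.DataFrame:
    """12 environmental layers on the grid, strongly cross-correlated.

    Three latent fields (a latitudinal gradient, a longitudinal gradient and
    a smooth spatially autocorrelated surface) are mixed into ``n_layers``
    observed layers with small independent noise, emulating the high
    collinearity of real climatic variables that motivates a PCA.
    """
    rng = np.random.default_rng(seed)
    centers = grid.cell_centers()
    nr, nc = grid.n_rows, grid.n_cols
    lat = centers[:, 1]
    lon = centers[:, 0]
    smooth = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=max(2, nr // 8))
    smooth = smooth.ravel()
    latents = np.column_stack([
        gradient_weight * (lat - lat.mean()) / max(lat.std(), 1e-9),
        gradient_weight * (lon - lon.mean()) / max(lon.std(), 1e-9),
        smooth / max(smooth.std(), 1e-9),
    ])[:, :n_latent]
    loadings = rng.standard_normal((n_latent, n_layers))
    loadings[0, 0] = 3.0  # first layer gradient-dominated
    layers = latents @ loadings + 0.3 * rng.standard_normal((grid.n_cells, n_layers))
    cols = [f"env{i + 1:02d}" for i in range(n_layers)]
    return pd.DataFrame(layers, index=pd.Index(grid.cell_ids(), name="cell_id"),
                        columns=cols)


def _parasite_labels(n: int) -> list[str]:
    return [f"p{i:04d}" for i in range(n)]


def richness_predictors(traits: pd.DataFrame, pam: grids.PresenceAbsenceMatrix,
                        ) -> pd.DataFrame:
    """The four richness predictors on the scales the GLM uses."""
    summ = grids.range_summaries(pam)
    df = summ["diversity_field"]
    ln_df = np.where(df > 0, np.log(df.where(df > 0, 1.0)), np.log1p(df))
    return pd.DataFrame({
        "ln_BM": np.log(traits["body_mass_g"].astype(float)),
        "ln_GR": np.log(summ["range_size_km2"]),
        "ln_DF": ln_df,
        "HB": traits["habitat_breadth"].astype(float),
    }, index=summ.index)


def generate_incidence(config: WorldConfig, seed: int,
                       predictors: pd.DataFrame | None = None,
                       dmatrix: DistanceMatrix | None = None,
                       max_retries: int = 20) -> pd.DataFrame:
    """Parasite x host binary incidence matrix from the planted model.

    richness mode — host i's richness is NB(mean = exp(X_i beta),
    dispersion nb_theta); that many distinct parasites are then assigned to
    the host uniformly at random.  sharing mode — each parasite gets a random
    focal host and infests every host i independently with probability
    expit(a_true + b_true * D(focal, i)) on the supplied normalized distance
    matrix.  An all-zero draw triggers a reseeded regeneration with warning.
    """
    rng = np.random.default_rng(seed)
    parasites = _parasite_labels(config.n_parasites)
    for attempt in range(max_retries):
        if config.mode == "richness":
            if predictors is None:
                raise ValueError("richness mode needs the predictor table")
            x = predictors[["ln_BM", "ln_GR", "ln_DF", "HB"]].to_numpy(float)
            if not np.isfinite(x).all():
                raise ValueError("undefined predictors")
            b0, *betas = config.richness_betas
            mean = np.exp(b0 + x @ np.asarray(betas))
            theta = config.nb_theta
            richness = rng.negative_binomial(theta, theta / (theta + mean))
            if (richness > config.n_parasites).any():
                warnings.warn("drawn richness exceeds the parasite pool; truncated")
                richness = np.minimum(richness, config.n_parasites)
            hosts = list(predictors.index)
            inc = np.zeros((config.n_parasites, len(hosts)), dtype=np.int8)
            for i in range(len(hosts)):
                if richness[i] > 0:
                    chosen = rng.choice(config.n_parasites, size=richness[i], replace=False)
                    inc[chosen, i] = 1
        else:
            if dmatrix is None:
                raise ValueError("sharing mode needs the driving distance matrix")
            if not dmatrix.normalized:
                raise ValueError("sharing mode needs a normalized distance matrix")
            hosts = list(dmatrix.labels)
            a_true, b_true = config.sharing_coefs
            d = dmatrix.values
            inc = np.zeros((config.n_parasites, len(hosts)), dtype=np.int8)
            focal = rng.integers(len(hosts), size=config.n_parasites)
            for p in range(config.n_parasites):
                prob = special.expit(a_true + b_true * d[focal[p]])
                inc[p] = rng.random(len(hosts)) < prob
        if inc.any():
            return pd.DataFrame(inc, index=pd.Index(parasites, name="parasite_id"),
                                columns=hosts)
        warnings.warn("all-zero incidence matrix; regenerating with a new substream")
    raise RuntimeError("could not generate a non-empty incidence matrix")


@dataclass
class SyntheticWorld:
    """A complete synthetic realm plus its planted truth."""

    config: WorldConfig
    tree: dendropy.Tree = field(repr=False)
    traits: pd.DataFrame = field(repr=False)
    pam: grids.PresenceAbsenceMatrix = field(repr=False)
    environment: pd.DataFrame = field(repr=False)
    incidence: pd.DataFrame = field(repr=False)
    predictors: pd.DataFrame = field(repr=False)
    driving_distance: DistanceMatrix | None = field(default=None, repr=False)

    @property
    def truth(self) -> dict:
        cfg = asdict(self.config)
        cfg["grid"] = self.config.grid.to_dict()
        return cfg


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate tree, traits, ranges, environment and incidence in one call.

    Substream seeds are derived from ``config.seed`` so stages are
    individually reproducible.
    """
    ss = np.random.SeedSequence(config.seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    tree = generate_phylogeny(config.n_hosts, sub[0])
    traits = generate_traits(tree, sub[1], config.trait_missing_frac)
    pam = generate_ranges(config.grid, config.n_hosts, sub[2],
                          config.range_median_cells, config.range_sigma)
    env = generate_environment(config.grid, sub[3])
    traits = traits.loc[pam.host_ids]
    summ = grids.range_summaries(pam)
    traits["range_size_km2"] = summ["range_size_km2"]
    preds = richness_predictors(traits, pam)

    dmat = None
    if config.mode == "sharing":
        dmat = _driving_distance(config, tree, traits, pam, env, summ)
        inc = generate_incidence(config, sub[4], dmatrix=dmat)
    else:
        inc = generate_incidence(config, sub[4], predictors=preds)
    return SyntheticWorld(config, tree, traits, pam, env, inc, preds, dmat)


def _driving_distance(config, tree, traits, pam, env, summ) -> DistanceMatrix:
    from . import distances as dst

    if config.sharing_distance == "phylo":
        return dst.phylogenetic_distance(tree)
    if config.sharing_distance == "trait":
        spec = dst.default_trait_spec(traits)
        dm = dst.gower_matrix(traits, spec)
        dm = dst.normalize01(dm)
        return DistanceMatrix(pam.host_ids, dm.to_frame().loc[pam.host_ids, pam.host_ids].to_numpy(),
                              kind="TD", normalized=True)
    if config.sharing_distance == "geo":
        cents = summ[["centroid_lon", "centroid_lat"]]
        return dst.geographic_distance(cents)
    profiles = dst.environmental_profiles(env, config.grid,
                                          summ[["centroid_lon", "centroid_lat"]])
    dm, _ = dst.env_pca_distance(profiles, n_components=3)
    return dm
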