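"""End-to-end orchestration: simulate (optional) -> range metrics ->
distance matrices -> richness GLM -> sharing analysis.

A :class:`RunConfig` (loadable from YAML) names every input and option; the
pipeline writes labeled CSV artifacts per stage plus a JSON run report, and
is byte-deterministic for a fixed config and seed.  Per-stage seeds are
derived from the global seed so stages can be rerun in isolation.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distances as dst
from . import grids, io, richness, sharing, simulate, trees

log = logging.getLogger("parafauna")

STAGES = ("simulate", "ranges", "distances", "richness", "sharing")


@dataclass
class RunConfig:
    outdir: str = "parafauna_out"
    seed: int = 0
    mode: str = "simulate"  # simulate | analyze
    # analyze-mode inputs
    tree_path: str | None = None
    traits_path: str | None = None
    pam_path: str | None = None
    environment_path: str | None = None
    incidence_path: str | None = None
    # grid
    grid: dict = field(default_factory=lambda: {"lon_min": 0, "lon_max": 20,
                                                "lat_min": 20, "lat_max": 40,
                                                "resolution": 1.0})
    # simulate-mode options
    n_hosts: int = 60
    n_parasites: int = 30
    sim_mode: str = "sharing"
    sharing_distance: str = "trait"
    # richness options
    aic_variant: str = "AIC"  # AIC | AICc
    signal_variant: str = "K*"
    n_perm: int = 199
    body_mass_col: str = "body_mass_g"
    habitat_breadth_col: str = "habitat_breadth"
    exclude_hosts: tuple[str, ...] = ()
    # distances options
    pca_components: int | None = 3
    pca_min_variance: float = 0.75
    env_buffer_km: float = 100.0
    # sharing options
    min_hosts: int = 6
    n_iter: int = 1000
    bootstrap_rule: str = "with_replacement"
    sharing_kinds: tuple[str, ...] = ("PD", "TD", "GD", "ED")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "analyze":
            required = {"tree_path": self.tree_path, "traits_path": self.traits_path,
                        "pam_path": self.pam_path,
                        "environment_path": self.environment_path,
                        "incidence_path": self.incidence_path}
            missing = [k for k, v in required.items() if not v]
            if missing:
                raise ValueError(f"analyze mode requires inputs: {missing}")
            gone = [k for k, v in required.items() if v and not Path(v).exists()]
            if gone:
                raise FileNotFoundError(f"missing input files: {gone}")

    def grid_spec(self) -> grids.GridSpec:
        return grids.GridSpec.from_dict(self.grid)


def _substreams(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(s.generate_state(1)[0] % (2**31 - 1))
            for name, s in zip(STAGES, ss)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written to JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _substreams(config.seed)
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {},
                    "warnings": [], "config": {k: v for k, v in asdict(config).items()}}
    manifest: list[str] = []

    def _save(name: str) -> Path:
        p = outdir / name
        manifest.append(name)
        return p

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            grid = config.grid_spec()

            # --- inputs: simulate or load -------------------------------
            if config.mode == "simulate":
                log.info("stage simulate: %d hosts, %d parasites",
                         config.n_hosts, config.n_parasites)
                world = simulate.generate_world(simulate.WorldConfig(
                    n_hosts=config.n_hosts, n_parasites=config.n_parasites,
                    grid=grid, seed=seeds["simulate"], mode=config.sim_mode,
                    sharing_distance=config.sharing_distance))
                tree, traits, pam = world.tree, world.traits, world.pam
                env, incidence = world.environment, world.incidence
                trees.write_newick(tree, _save("tree.nwk"))
                io.write_table(traits, _save("traits.csv"))
                io.write_pam(pam, _save("presence_absence.csv"))
                io.write_table(env, _save("environment.csv"))
                io.write_table(incidence, _save("incidence.csv"))
                io.write_json(world.truth, _save("planted_truth.json"))
                report["stages"]["simulate"] = {"n_hosts": pam.n_hosts,
                                                "n_parasites": len(incidence)}
            else:
                tree = trees.read_newick(config.tree_path)
                traits = io.read_traits(config.traits_path)
                pam = io.read_pam(config.pam_path, grid)
                env = io.read_environment(config.environment_path)
                incidence = io.read_incidence(config.incidence_path)

            # --- range metrics ------------------------------------------
            log.info("stage ranges")
            summ = grids.range_summaries(pam)
            io.write_table(summ, _save("range_summary.csv"))
            report["stages"]["ranges"] = {"n_hosts": len(summ)}

            # --- distance matrices --------------------------------------
            log.info("stage distances")
            tree_u = trees.ultrametrize_extend(trees.resolve_polytomies(
                tree, seeds["distances"]))
            pd_mat = dst.phylogenetic_distance(tree_u)
            spec = dst.default_trait_spec(traits)
            td_full = dst.normalize01(dst.gower_matrix(traits, spec))
            cents = summ[["centroid_lon", "centroid_lat"]]
            gd_mat = dst.geographic_distance(cents)
            profiles = dst.environmental_profiles(env, grid, cents,
                                                  config.env_buffer_km)
            ed_mat, pca_report = dst.env_pca_distance(
                profiles, n_components=config.pca_components,
                min_variance=config.pca_min_variance)
            order = pam.host_ids
            mats = {}
            for dm in (pd_mat, td_full, gd_mat, ed_mat):
                f = dm.to_frame().loc[order, order]
                mats[dm.kind] = dst.DistanceMatrix(order, f.to_numpy(), dm.kind,
                                                   normalized=True)
            for kind, dm in mats.items():
                rep = pca_report if kind == "ED" else None
                io.write_distance_matrix(dm, _save(f"distance_{kind}.csv"),
                                         _save(f"distance_{kind}.json"), rep)
            report["stages"]["distances"] = {"kinds": list(mats),
                                             "pca": pca_report}

            # --- richness GLM -------------------------------------------
            log.info("stage richness")
            dataset = richness.build_richness_dataset(
                incidence, traits, summ, config.body_mass_col,
                config.habitat_breadth_col, config.exclude_hosts)
            io.write_table(dataset, _save("richness_dataset.csv"))
            tip_labels = {leaf.taxon.label for leaf in tree_u.leaf_node_iter()}
            if tip_labels != set(dataset.index):
                tree_u = tree_u.extract_tree_with_taxa_labels(labels=set(dataset.index))
            sig = richness.blomberg_k(tree_u, dataset["richness"].astype(float),
                                      config.signal_variant, config.n_perm,
                                      seeds["richness"])
            if sig.p_value < 0.05:
                warnings.warn(
                    f"significant phylogenetic signal in richness "
                    f"({sig.variant} = {sig.statistic:.3f}, p = {sig.p_value:.3f}); "
                    "models are fitted without phylogenetic correction")
            table, best = richness.all_subsets_select(
                dataset, use_aicc=(config.aic_variant == "AICc"))
            io.write_table(table.set_index("predictors"), _save("model_selection.csv"))
            io.write_json({
                "best_predictors": list(best.predictors),
                "coefficients": best.coefficients.to_dict(),
                "theta": best.theta,
                "logLik": best.log_likelihood,
                "AIC": best.aic,
                "explained_deviance_percent": best.explained_deviance_percent,
                "nagelkerke_r2": best.nagelkerke_r2,
                "signal": {"variant": sig.variant, "statistic": sig.statistic,
                           "p_value": sig.p_value, "n_perm": sig.n_permutations},
            }, _save("richness_best_model.json"))
            report["stages"]["richness"] = {"n_hosts": len(dataset),
                                            "n_models": len(table),
                                            "best": list(best.predictors)}

            # --- sharing ------------------------------------------------
            log.info("stage sharing")
            share_report = {}
            pooled_rows = []
            d_grid = np.linspace(0, 1, 101)
            for k, kind in enumerate(config.sharing_kinds):
                fit = sharing.pooled_coefficients(
                    incidence, mats[kind], n_iter=config.n_iter,
                    seed=seeds["sharing"] + k, min_hosts=config.min_hosts,
                    bootstrap=config.bootstrap_rule)
                io.write_table(fit.per_parasite.set_index("parasite_id"),
                               _save(f"sharing_per_parasite_{kind}.csv"))
                io.write_table(
                    pd.DataFrame({"intercept": fit.bootstrap_intercepts,
                                  "slope": fit.bootstrap_slopes}).rename_axis("iteration"),
                    _save(f"sharing_bootstrap_{kind}.csv"))
                curve = sharing.sharing_probability(fit.pooled_intercept,
                                                    fit.pooled_slope, d_grid)
                io.write_table(pd.DataFrame({"D": d_grid, "P": curve}).set_index("D"),
                               _save(f"sharing_curve_{kind}.csv"))
                pooled_rows.append({"distance": kind,
                                    "mean_intercept": fit.pooled_intercept,
                                    "mean_slope": fit.pooled_slope,
                                    "PNS": fit.pns,
                                    "n_eligible": len(fit.per_parasite)})
                share_report[kind] = pooled_rows[-1]
            io.write_table(pd.DataFrame(pooled_rows).set_index("distance"),
                           _save("sharing_pooled.csv"))
            report["stages"]["sharing"] = share_report

            report["warnings"] = sorted({str(w.message) for w in caught})
    except Exception:
        (outdir / "MANIFEST").write_text(
            "\n".join(["# INCOMPLETE RUN"] + manifest) + "\n")
        raise
    (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")
    io.write_json(report, outdir / "run_report.json")
    return report
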