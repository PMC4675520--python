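"""The end-to-end pipeline driver.

Chains simulate -> popgen -> divmap -> niche -> sdm -> prioritize,
persisting every intermediate artifact (CSV tables, ESRI ASCII rasters,
a run log with a config echo) in one output directory, so stages can
also be run individually against an existing directory. All randomness
derives from the config seed; two runs with the same seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import divmap, io, niche, popgen, prioritize, synth
from .config import PipelineConfig
from .raster import read_ascii_grid, write_ascii_grid
from .sdm import EnsembleSDM, sample_background, summarize_scenarios
from .stack import EnvStack

__all__ = ["Pipeline", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class Pipeline:
    def __init__(self, config: PipelineConfig, outdir):
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.cfg.to_toml(self.outdir / "config.toml")

    def log(self, msg: str) -> None:
        with open(self.outdir / "run.log", "a") as fh:
            fh.write(msg + "\n")

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.cfg
        world = synth.generate_world(
            cfg.seed, cfg.n_env_vars, cfg.extent, cfg.resolution_arcmin,
            cfg.n_refugia, cfg.refugium_radius_deg, cfg.n_alt_climates,
        )
        points = synth.generate_presences(
            world, cfg.n_wild, cfg.n_cult, cfg.niche_shift
        )
        self.log(f"simulate: {len(points)} presence points "
                 f"({cfg.n_wild} wild, {cfg.n_cult} cultivated)")
        # genotype the wild points plus the first block of cultivated points,
        # mirroring a collection where only part of the material is genotyped
        geno_points = pd.concat(
            [
                points[points["variety"] == "wild"],
                points[points["variety"] == "cultivated"].head(cfg.n_cult_genotyped),
            ],
            ignore_index=True,
        )
        table = synth.generate_genotypes(
            geno_points, cfg.n_loci, (cfg.alleles_min, cfg.alleles_max),
            cfg.private_allele_rate, cfg.ibd_scale_deg, world.refugia,
            seed=cfg.seed,
        )
        cult_geno = geno_points[geno_points["variety"] == "cultivated"]
        traits = synth.generate_traits(cult_geno, cfg.n_traits, seed=cfg.seed)
        self.log(f"simulate: genotyped {table.n} individuals at {len(table.loci)} loci; "
                 f"traits for {len(traits)} cultivated individuals")
        io.write_points(points, self.outdir / "points.csv")
        io.write_points(geno_points, self.outdir / "genotyped_points.csv")
        io.write_genotypes(table, self.outdir / "genotypes.csv")
        io.write_traits(traits, self.outdir / "traits.csv")
        world.env_current.write_dir(self.outdir / "env_current")
        for name, stack in world.env_alt.items():
            stack.write_dir(self.outdir / f"env_{name}")
        pd.DataFrame(
            [{"name": r.name, "lon": r.lon, "lat": r.lat, "radius_deg": r.radius_deg}
             for r in world.refugia]
        ).to_csv(self.outdir / "refugia.csv", index=False)
        np.savetxt(self.outdir / "suitability_weights.txt", world.suitability_weights)

    def _load_genotypes(self):
        pts = io.read_points(self.outdir / "genotyped_points.csv")
        return pts, io.read_genotypes(self.outdir / "genotypes.csv", pts)

    def run_popgen(self) -> None:
        _, table = self._load_genotypes()
        summaries = popgen.locus_summaries(table)
        summaries.to_csv(self.outdir / "locus_summaries.csv")
        geo = popgen.geographic_distance_matrix(table)
        gen = popgen.allele_sharing_distance(table)
        r, p = popgen.mantel_test(geo, gen, permutations=999, seed=self.cfg.seed)
        pd.DataFrame([{"r": r, "p": p, "permutations": 999}]).to_csv(
            self.outdir / "mantel.csv", index=False
        )
        self.log(f"popgen: {len(summaries)} loci summarized; Mantel r={r:.3f} p={p:.4f}")

    def run_divmap(self) -> None:
        cfg = self.cfg
        pts, table = self._load_genotypes()
        traits = io.read_traits(self.outdir / "traits.csv")
        grid = EnvStack.read_dir(self.outdir / "env_current").grid.like()
        assignment = divmap.assign_neighborhoods(
            pts, grid, cfg.neighborhood_diameter_deg
        )
        occupied = assignment.occupied()
        self.log(f"divmap: {len(occupied)} occupied cells")
        catalog = popgen.classify_lca(
            table, occupied, cfg.lca_freq, cfg.lca_area
        )
        catalog.entries.to_csv(self.outdir / "lca_catalog.csv", index=False)
        spec = divmap.BootstrapSpec(cfg.sample_size, cfg.replicates, cfg.seed)
        rasters = {
            "richness": divmap.make_richness_stat(table),
            "ho": divmap.make_ho_stat(table),
            "lca_richness": divmap.make_lca_richness_stat(table, catalog),
        }
        for name, stat in rasters.items():
            r = divmap.cell_statistic_bootstrap(assignment, stat, spec)
            write_ascii_grid(r, self.outdir / f"{name}.asc")
            write_ascii_grid(
                divmap.standardize_raster(r), self.outdir / f"{name}_std.asc"
            )
        # phenotypic variation: two collections mapped separately, compared,
        # standardized and max-merged (traits cover cultivated material only)
        cult_ids = list(traits.index)
        half = len(cult_ids) // 2
        cols = {"a": cult_ids[:half], "b": cult_ids[half:]}
        cv_rasters = {}
        for key, ids in cols.items():
            sub_pts = pts[pts["id"].isin(ids)]
            sub_assign = divmap.assign_neighborhoods(
                sub_pts, grid, cfg.neighborhood_diameter_deg
            )
            stat = divmap.make_cv_stat(traits)
            r = divmap.cell_statistic_bootstrap(sub_assign, stat, spec)
            cv_rasters[key] = r
            write_ascii_grid(r, self.outdir / f"cv_{key}.asc")
        cmp_res = divmap.compare_collection_cvs(
            cv_rasters["a"].valid_values, cv_rasters["b"].valid_values
        )
        pd.DataFrame([cmp_res._asdict()]).to_csv(
            self.outdir / "cv_comparison.csv", index=False
        )
        merged = divmap.merge_rasters_max(
            divmap.standardize_raster(cv_rasters["a"]),
            divmap.standardize_raster(cv_rasters["b"]),
        )
        write_ascii_grid(merged, self.outdir / "cv_merged_std.asc")
        self.log(
            f"divmap: CV collections F={cmp_res.F:.3f} (p={cmp_res.p_f:.3f}), "
            f"t={cmp_res.t:.3f} (p={cmp_res.p_t:.3f})"
        )

    def run_niche(self) -> None:
        cfg = self.cfg
        points = io.read_points(self.outdir / "points.csv")
        env = EnvStack.read_dir(self.outdir / "env_current")
        space = niche.pca_env(points, env)
        kept = points.iloc[space.kept].reset_index(drop=True)
        scores = pd.DataFrame(space.scores, columns=["pc1", "pc2"])
        scores.insert(0, "id", kept["id"])
        scores["variety"] = kept["variety"]
        scores.to_csv(self.outdir / "pca_scores.csv", index=False)
        wild = space.scores[(kept["variety"] == "wild").to_numpy()]
        cult = space.scores[(kept["variety"] == "cultivated").to_numpy()]
        hull = niche.build_hull(wild, cfg.hull_buffer)
        inside, outside = niche.filter_in_niche(hull, cult)
        self.log(
            f"niche: PCA explains {space.explained[:2].sum():.1%}; "
            f"{inside.size}/{len(cult)} cultivated points inside the wild niche hull"
        )
        cult_ids = kept.loc[(kept["variety"] == "cultivated").to_numpy(), "id"].to_numpy()
        pd.DataFrame(
            {"id": cult_ids, "in_niche": np.isin(np.arange(len(cult)), inside)}
        ).to_csv(self.outdir / "niche_filter.csv", index=False)
        d_obs, p_eq = niche.niche_equivalency_test(
            wild, cult, permutations=cfg.niche_permutations, seed=cfg.seed,
            resolution=cfg.density_resolution,
        )
        X, _ = env.cell_table()
        # background for the similarity null: all valid cells in PC space
        from sklearn.preprocessing import StandardScaler

        vals = env.extract(kept["lon"].to_numpy(), kept["lat"].to_numpy())
        scaler = StandardScaler().fit(vals.to_numpy(dtype=float))
        bg_scores = scaler.transform(X) @ space.loadings
        _, p_sim = niche.niche_similarity_test(
            wild, cult, bg_scores, permutations=cfg.niche_permutations,
            seed=cfg.seed, resolution=cfg.density_resolution,
        )
        pd.DataFrame(
            [{"schoeners_d": d_obs, "p_equivalency": p_eq, "p_similarity": p_sim,
              "explained_pc1": space.explained[0], "explained_pc2": space.explained[1]}]
        ).to_csv(self.outdir / "niche_overlap.csv", index=False)
        self.log(f"niche: Schoener's D={d_obs:.3f}, "
                 f"p_equivalency={p_eq:.3f}, p_similarity={p_sim:.3f}")

    def run_sdm(self) -> None:
        cfg = self.cfg
        points = io.read_points(self.outdir / "points.csv")
        env_dir = self.outdir / "env_current"
        if not env_dir.exists():
            raise FileNotFoundError(f"missing environment directory {env_dir}")
        env = EnvStack.read_dir(env_dir)
        presences = points[points["variety"] == "cultivated"].reset_index(drop=True)
        n_valid = int(env.valid_mask().sum())
        n_bg = min(cfg.background_factor * len(presences), cfg.background_cap, n_valid)
        background = sample_background(
            env.grid.like(np.where(env.valid_mask(), 1.0, np.nan)), n_bg, cfg.seed
        )
        model = EnsembleSDM(
            presences, background, env,
            k=cfg.k_folds, repeats=cfg.cv_repeats, alpha=cfg.alpha,
            ssb_tolerance=cfg.ssb_tolerance,
        )
        res = model.fit(seed=cfg.seed)
        res.evaluation_table.to_csv(self.outdir / "evaluation.csv", index=False)
        (self.outdir / "sdm_summary.txt").write_text(res.summary() + "\n")
        self.log("sdm:\n" + res.summary())
        if res.ensemble is None:
            raise RuntimeError("no model outperformed the geographic null")
        with open(self.outdir / "ensemble.json", "w") as fh:
            json.dump(
                {
                    "members": res.ensemble.members,
                    "weights": list(res.ensemble.weights),
                    "threshold": res.threshold,
                    "retained": res.retained,
                    "mean_cauc": {m: e.mean_cauc for m, e in res.evals.items()},
                },
                fh, indent=2,
            )
        current = res.project()
        write_ascii_grid(current, self.outdir / "suitability_current.asc")
        alt_maps = []
        for alt_dir in sorted(self.outdir.glob("env_alt*")):
            alt_env = EnvStack.read_dir(alt_dir)
            m = res.project(alt_env)
            write_ascii_grid(m, self.outdir / f"suitability_{alt_dir.name[4:]}.asc")
            alt_maps.append(m)
        if alt_maps:
            avg = summarize_scenarios(alt_maps, res.threshold, restrict=True)
            write_ascii_grid(avg, self.outdir / "suitability_alt_avg.asc")

    def run_prioritize(self) -> None:
        cfg = self.cfg
        now = read_ascii_grid(self.outdir / "suitability_current.asc")
        future = read_ascii_grid(self.outdir / "suitability_alt_avg.asc")
        cutoff_rows = []
        for tag, div_name in (("genetic", "richness.asc"), ("phenotypic", "cv_merged_std.asc")):
            diversity = read_ascii_grid(self.outdir / div_name)
            mask = prioritize.intersect_priority(
                [("suitability_now", now), ("suitability_future", future),
                 (div_name.removesuffix(".asc"), diversity)],
                cfg.quartile,
            )
            write_ascii_grid(mask.to_raster(), self.outdir / f"priority_{tag}.asc")
            for name, cutoff in mask.inputs:
                cutoff_rows.append({"analysis": tag, "layer": name, "cutoff": cutoff})
            self.log(f"prioritize: {mask.n_priority} {tag}-priority cells")
        pd.DataFrame(cutoff_rows).to_csv(self.outdir / "priority_cutoffs.csv", index=False)

    # -- driver -------------------------------------------------------------

    STAGES = ("simulate", "popgen", "divmap", "niche", "sdm", "prioritize")

    def run_stage(self, stage: str) -> None:
        fn = {
            "simulate": self.simulate,
            "popgen": self.run_popgen,
            "divmap": self.run_divmap,
            "niche": self.run_niche,
            "sdm": self.run_sdm,
            "prioritize": self.run_prioritize,
        }[stage]
        try:
            fn()
        except Exception as exc:
            self.log(f"HALT at stage {stage}: {exc}")
            raise PipelineError(stage, exc) from exc

    def run_all(self) -> Path:
        self.log(f"run started: seed={self.cfg.seed}")  # no timestamp: artifacts
        # must be byte-identical across reruns with the same seed
        for stage in self.STAGES:
            self.run_stage(stage)
        self.log("run completed")
        return self.outdir


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage with the given config; returns the artifact directory."""
    return Pipeline(config, outdir).run_all()
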