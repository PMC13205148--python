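"""End-to-end pipeline orchestration with a reproducibility manifest.

Runs the requested stages — simulate, blup, diversity, distances, mantel,
gwas, cluster, njtree, select — in dependency order, writing each stage's
tables under the output directory and a manifest recording package version,
seeds, parameters, and input hashes. Reruns with an identical configuration
produce identical numeric outputs.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import blup as blup_mod
from . import cluster as cluster_mod
from . import distance as dist_mod
from . import diversity as div_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import njtree as nj_mod
from . import select as select_mod
from .simulate import SimConfig, simulate_genotypes, simulate_phenotypes

ALL_STAGES = ("simulate", "blup", "diversity", "distances", "mantel",
              "gwas", "cluster", "njtree", "select")


@dataclass
class RunConfig:
    out_dir: str = "results/pipeline"
    vcf: str | None = None              # simulate when absent
    pheno: str | None = None
    annotations: str | None = None      # CSV: line_id, clade, ancestry, ...
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    sim: SimConfig | None = None
    n_perm: int = 999
    gwas_trait: str = "PH"
    k_range: tuple[int, int] = (2, 8)
    n_stage1: int = 50
    n_final: int = 30
    w_topsis: float = 0.8
    w_mnnd: float = 0.2
    mnnd_mode: str = "mean-all"

    def to_manifest(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in asdict(self.sim).items()}
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "package": "maizecore",
        "version": __version__,
        "python": sys.version.split()[0],
        "config": config.to_manifest(),
        "config_hash": io_mod.config_hash(config.to_manifest()),
        "seeds": {"master": config.seed, "mantel": config.seed + 1,
                  "kmeans": config.seed + 2},
        "stages_run": [],
        "stages_skipped": [],
        "input_hashes": {},
    }
    stage = "setup"
    try:
        geno = pheno = None
        if "simulate" in config.stages and config.vcf is None:
            stage = "simulate"
            sim = config.sim or SimConfig(seed=config.seed)
            geno, truth = simulate_genotypes(sim)
            pheno = simulate_phenotypes(geno, truth, sim)
            io_mod.write_vcf(geno, out / "genotypes.vcf")
            io_mod.write_phenotypes(pheno, out / "phenotypes.csv")
            io_mod.write_json(truth.to_dict(), out / "truth.json")
            manifest["stages_run"].append(stage)
        if config.vcf is not None:
            stage = "read-inputs"
            geno = io_mod.read_vcf(config.vcf)
            manifest["input_hashes"]["vcf"] = io_mod.config_hash(
                Path(config.vcf).read_text())
        if config.pheno is not None:
            pheno = io_mod.read_phenotypes(config.pheno)
            manifest["input_hashes"]["pheno"] = io_mod.config_hash(
                Path(config.pheno).read_text())
        results["geno"], results["pheno"] = geno, pheno

        blups = None
        if "blup" in config.stages:
            if pheno is None:
                manifest["stages_skipped"].append("blup (no phenotypes)")
            else:
                stage = "blup"
                models = blup_mod.fit_all_traits(pheno)
                blups = blup_mod.extract_blups(models)
                blups.to_csv(out / "blups.csv")
                io_mod.write_json(
                    {t: {"var": m.components,
                         "proportions": blup_mod.variance_proportions(m)}
                     for t, m in models.items()},
                    out / "variance_components.json",
                )
                results["blup_models"], results["blups"] = models, blups
                manifest["stages_run"].append(stage)

        if "diversity" in config.stages:
            stage = "diversity"
            groups = None
            if blups is not None:
                groups = pd.Series([io_mod.line_type(l) for l in blups.index],
                                   index=blups.index)
                summary = div_mod.cv_table(blups, groups)
                summary.to_csv(out / "trait_summary.tsv", sep="\t", index=False)
                r, p, stars = div_mod.pearson_matrix(blups)
                r.to_csv(out / "pearson_r.tsv", sep="\t")
                stars.to_csv(out / "pearson_stars.tsv", sep="\t")
                sh = {
                    t: div_mod.shannon_index(blups[t], div_mod.sturges_k(len(blups))).H
                    for t in blups.columns
                }
                io_mod.write_json(sh, out / "shannon.json")
                results["trait_summary"] = summary
            if geno is not None:
                ggroups = [io_mod.line_type(l) for l in geno.line_ids]
                stats = div_mod.locus_stats(geno, ggroups)
                io_mod.write_json({k: v.summary() for k, v in stats.items()},
                                  out / "snp_diversity.json")
                results["locus_stats"] = stats
            manifest["stages_run"].append(stage)

        gdist = pdist_ = None
        if "distances" in config.stages and geno is not None:
            stage = "distances"
            gdist = dist_mod.genotype_distance(geno)
            dist_mod.write_distance_tsv(gdist, out / "geno_dist.tsv")
            if blups is not None:
                pdist_ = dist_mod.phenotype_distance(blups)
                dist_mod.write_distance_tsv(pdist_, out / "pheno_dist.tsv")
            results["geno_dist"], results["pheno_dist"] = gdist, pdist_
            manifest["stages_run"].append(stage)

        if "mantel" in config.stages:
            if gdist is None or pdist_ is None:
                manifest["stages_skipped"].append("mantel (needs both distances)")
            else:
                stage = "mantel"
                rows = [{"trait": "overall",
                         **asdict(dist_mod.mantel_test(
                             gdist, pdist_, config.n_perm, config.seed + 1))}]
                for t in blups.columns:
                    dt = dist_mod.phenotype_distance(blups, [t])
                    rows.append({"trait": t,
                                 **asdict(dist_mod.mantel_test(
                                     gdist, dt, config.n_perm, config.seed + 1))})
                mantel_df = pd.DataFrame(rows)
                mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False)
                results["mantel"] = mantel_df
                manifest["stages_run"].append(stage)

        if "gwas" in config.stages:
            if geno is None or blups is None or config.gwas_trait not in blups:
                manifest["stages_skipped"].append("gwas (needs genotypes + trait BLUPs)")
            else:
                stage = "gwas"
                y = blups[config.gwas_trait].to_numpy()
                K = gwas_mod.compute_kinship(geno)
                scan = gwas_mod.association_scan(geno, y, K=K)
                scan.table.to_csv(out / f"gwas_{config.gwas_trait}.tsv",
                                  sep="\t", index=False)
                gwas_mod.qq_data(scan).to_csv(
                    out / f"gwas_{config.gwas_trait}_qq.tsv", sep="\t", index=False)
                results["gwas"] = scan
                manifest["stages_run"].append(stage)

        if "cluster" in config.stages and blups is not None:
            stage = "cluster"
            Z = (blups - blups.mean()) / blups.std(ddof=1)
            pca_p = cluster_mod.pca(blups, standardize=True)
            pca_p.scores.iloc[:, :5].to_csv(out / "pheno_pca_scores.tsv", sep="\t")
            pca_p.loadings.iloc[:, :5].to_csv(out / "pheno_pca_loadings.tsv", sep="\t")
            km = cluster_mod.kmeans_select(
                Z, range(config.k_range[0], config.k_range[1] + 1),
                seed=config.seed + 2)
            km.assignments.to_csv(out / "kmeans_clusters.tsv", sep="\t")
            results["pca_pheno"], results["kmeans"] = pca_p, km
            if geno is not None:
                gm = geno.masked().filled(0.0)
                pca_g = cluster_mod.pca(
                    pd.DataFrame(gm, index=geno.line_ids), standardize=False)
                pca_g.scores.iloc[:, :5].to_csv(out / "geno_pca_scores.tsv", sep="\t")
                results["pca_geno"] = pca_g
            results["bicluster"] = cluster_mod.hierarchical_bicluster(blups)
            manifest["stages_run"].append(stage)

        if "njtree" in config.stages:
            if gdist is None:
                manifest["stages_skipped"].append("njtree (needs genotype distances)")
            else:
                stage = "njtree"
                tree = nj_mod.nj_tree(gdist)
                (out / "nj_tree.nwk").write_text(tree.newick() + "\n")
                results["nj_tree"] = tree
                manifest["stages_run"].append(stage)

        if "select" in config.stages:
            if gdist is None or blups is None:
                manifest["stages_skipped"].append("select (needs distances + BLUPs)")
            else:
                stage = "select"
                tcfg = select_mod.TraitConfig.from_cv(blups)
                topsis = select_mod.topsis_scores(blups, tcfg)
                mnnd = select_mod.mnnd_scores(gdist, mode=config.mnnd_mode)
                n = len(topsis)
                sel = select_mod.composite_select(
                    topsis, mnnd, config.w_topsis, config.w_mnnd,
                    min(config.n_stage1, n), min(config.n_final, n))
                ann = None
                if config.annotations:
                    ann = pd.read_csv(config.annotations, index_col="line_id")
                report = select_mod.core_report(sel, blups, ann)
                report["table"].to_csv(out / "core_selection.tsv", sep="\t")
                io_mod.write_json(report["summary"], out / "core_summary.json")
                results["selection"], results["core_report"] = sel, report
                manifest["stages_run"].append(stage)
    except Exception as err:
        io_mod.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {err}") from err

    io_mod.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
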