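"""End-to-end analysis: genotype file in, figure/table products out.

``run_full_analysis`` executes the whole workflow in order — allele
frequencies and heterozygosity, the Hardy-Weinberg scan, per-locus
distance matrices with the inter-locus Mantel grid, multilocus D_A/D_C
matrices, neighbor-joining trees with bootstrap-over-loci support and a
consensus of replicate trees, PCA with parallel analysis and the
PC-score-vs-geography Mantel test, admixture clustering over a K range
with run alignment, and the genetic/geographic/linguistic Mantel table
with language-group exclusion rows.  Both dataset subsets produced by
the 40% missing-rate policy are always generated: the full-loci subset
(all loci, populations with complete marker information) carries the
multi-locus analyses, and the full-population subset (all populations,
clean loci only) establishes every population's position.

Every product is plain text (CSV / Newick / PHYLIP) with the config
hash in a header comment; all stage seeds derive from one root seed, so
a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import admixture as adm
from . import dataset as dsmod
from .dataset import GenotypeDataset, PopulationMeta, allele_frequencies, subset_by_missing_policy
from .distance import DistanceMatrix, bootstrap_over_loci, pairwise_matrix
from .diversity import heterozygosity_summary, hwe_scan, write_hwe_report
from .geo_lang import LanguageTree, geographic_distance_matrix, linguistic_distance_matrix
from .mantel import exclusion_analysis, mantel
from .pca import normalize_frequencies, parallel_analysis, pc_score_distances, pca
from .phylogeny import bipartition_support, majority_rule_consensus, neighbor_joining
from .study import DEFAULT_LANGUAGE_TREE, LANGUAGE_GROUP

log = logging.getLogger("strpop.pipeline")

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """All knobs of a full run; every stage seed derives from ``seed``."""

    genotypes: str | Path | None = None
    dialect: str = "structure_format"
    metadata: str | Path | None = None
    language_tree: str | Path | None = None
    out_dir: str | Path = "strpop_out"
    tolerance: float = 0.40
    measures: tuple[str, ...] = ("DA", "DC")
    bootstrap_B: int = 1000
    permutations: int = 5000
    pca_components: int = 2
    parallel_reps: int = 10_000
    admixture_K: tuple[int, ...] = (2, 3, 4)
    admixture_runs: int = 3
    admixture_burn_in: int = 2000
    admixture_run_length: int = 2000
    hwe_chain_steps: int = 20_000
    hwe_burn_in: int = 2000
    seed: int = 0

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True,
               index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        frame.to_csv(fh, index=index, index_label=index_label)


def _stage_seed(root: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_full_analysis(
    cfg: AnalysisConfig,
    ds: GenotypeDataset | None = None,
    populations: Sequence[PopulationMeta] | None = None,
    tree: LanguageTree | None = None,
) -> dict:
    """Run every stage and write the report bundle to ``cfg.out_dir``.

    Inputs may be given as paths in *cfg* or as in-memory objects; the
    latter win.  Returns a dict with the product paths (``products``)
    and the main in-memory results.  A stage failure writes a partial
    manifest before the exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    products: dict[str, str] = {}
    results: dict = {"products": products, "config_hash": h}
    manifest = {"config_hash": h, "completed": [], "failed": None}

    def record(stage: str, paths: dict[str, Path]) -> None:
        for k, p in paths.items():
            products[k] = str(p)
        manifest["completed"].append(stage)

    stage = "load"
    try:
        t0 = time.time()
        if ds is None:
            if cfg.genotypes is None:
                raise ValueError("no genotype input supplied")
            metas = (
                dsmod.read_population_metadata(cfg.metadata) if cfg.metadata else None
            )
            ds = dsmod.read_genotypes(cfg.genotypes, cfg.dialect, populations=metas)
        if populations is None:
            populations = ds.populations
        if tree is None:
            if cfg.language_tree:
                tree = LanguageTree.from_yaml(cfg.language_tree)
            else:
                mapping = {
                    p.name: (p.lineage[-2] if len(p.lineage) >= 2 else LANGUAGE_GROUP.get(p.name, ""))
                    for p in populations
                }
                tree = LanguageTree(DEFAULT_LANGUAGE_TREE, mapping)
        manifest["completed"].append(stage)

        # ------------------------------------------------ subsets
        stage = "subset"
        full_loci, full_population = subset_by_missing_policy(ds, cfg.tolerance)
        log.info("subsets: full-loci %d pops, full-population %d loci",
                 len(full_loci.population_names), full_population.n_loci)
        manifest["completed"].append(stage)

        # ------------------------------------------------ frequencies + H_E
        stage = "frequencies"
        table_fl = allele_frequencies(full_loci)
        table_fp = allele_frequencies(full_population)
        het = heterozygosity_summary(allele_frequencies(ds), cfg.tolerance)
        table_fl.write_csv(out / "frequencies_full_loci.csv")
        _write_csv(het.values, out / "heterozygosity.csv", h, index_label="population")
        _write_csv(het.per_locus, out / "heterozygosity_per_locus.csv", h, index_label="locus")
        record(stage, {"frequencies": out / "frequencies_full_loci.csv",
                       "heterozygosity": out / "heterozygosity.csv",
                       "heterozygosity_per_locus": out / "heterozygosity_per_locus.csv"})
        results["heterozygosity"] = het

        # ------------------------------------------------ HWE scan
        stage = "hwe"
        pvals = hwe_scan(ds, chain_steps=cfg.hwe_chain_steps, burn_in=cfg.hwe_burn_in,
                         seed=_stage_seed(cfg.seed, stage))
        write_hwe_report(pvals, out / "hwe_pvalues.csv")
        record(stage, {"hwe": out / "hwe_pvalues.csv"})
        results["hwe_pvalues"] = pvals

        # ------------------------------------------------ per-locus distances + Mantel grid
        stage = "locus_mantel"
        loci = full_loci.locus_names
        per_locus = {l: pairwise_matrix(table_fl, "DA", loci=[l]) for l in loci}
        grid_r = pd.DataFrame(np.nan, index=loci, columns=loci)
        grid_p = pd.DataFrame(np.nan, index=loci, columns=loci)
        rng = np.random.default_rng(_stage_seed(cfg.seed, stage))
        for a in range(len(loci)):
            for b in range(a + 1, len(loci)):
                res = mantel(per_locus[loci[a]], per_locus[loci[b]],
                             permutations=cfg.permutations, seed=int(rng.integers(2**31)))
                grid_r.iloc[a, b] = grid_r.iloc[b, a] = res.r
                grid_p.iloc[a, b] = grid_p.iloc[b, a] = res.p_value
        _write_csv(grid_r, out / "locus_mantel_r.csv", h, index_label="locus")
        _write_csv(grid_p, out / "locus_mantel_p.csv", h, index_label="locus")
        record(stage, {"locus_mantel_r": out / "locus_mantel_r.csv",
                       "locus_mantel_p": out / "locus_mantel_p.csv"})
        results["locus_mantel_r"] = grid_r

        # ------------------------------------------------ multilocus distances
        stage = "distances"
        dist: dict[tuple[str, str], DistanceMatrix] = {}
        for measure in cfg.measures:
            for name, tab in (("full_loci", table_fl), ("full_population", table_fp)):
                m = pairwise_matrix(tab, measure)
                dist[(measure, name)] = m
                m.to_phylip(out / f"dist_{measure}_{name}.phy")
                products[f"dist_{measure}_{name}"] = str(out / f"dist_{measure}_{name}.phy")
        manifest["completed"].append(stage)
        results["distances"] = dist

        # ------------------------------------------------ trees
        stage = "trees"
        tree_paths = {}
        for name, tab in (("full_loci", table_fl), ("full_population", table_fp)):
            boot = bootstrap_over_loci(tab, "DA", B=cfg.bootstrap_B,
                                       seed=_stage_seed(cfg.seed, f"boot_{name}"))
            ref = neighbor_joining(dist[("DA", name)])
            supported = bipartition_support(ref, [neighbor_joining(m) for m in boot.replicates])
            p = out / f"nj_DA_{name}.nwk"
            p.write_text(supported.to_newick(clamp_negative=True) + "\n")
            tree_paths[f"nj_DA_{name}"] = p
            results[f"nj_DA_{name}"] = supported
            if "DC" in cfg.measures:
                boot_dc = bootstrap_over_loci(tab, "DC", B=cfg.bootstrap_B,
                                              seed=_stage_seed(cfg.seed, f"bootdc_{name}"))
                cons = majority_rule_consensus(
                    [neighbor_joining(m) for m in boot_dc.replicates]
                )
                p2 = out / f"nj_DC_consensus_{name}.nwk"
                p2.write_text(cons.to_newick() + "\n")
                tree_paths[f"nj_DC_consensus_{name}"] = p2
                results[f"nj_DC_consensus_{name}"] = cons
        record(stage, tree_paths)

        # ------------------------------------------------ PCA + parallel analysis
        stage = "pca"
        norm, dropped = normalize_frequencies(table_fl)
        pres = pca(norm)
        _write_csv(pres.scores, out / "pca_scores.csv", h, index_label="population")
        contrib = pd.DataFrame({"percent_variance": pres.percent_variance},
                               index=[f"PC{k+1}" for k in range(len(pres.percent_variance))])
        par = parallel_analysis(
            n_obs=norm.shape[0], n_vars=norm.shape[1], reps=cfg.parallel_reps,
            seed=_stage_seed(cfg.seed, "parallel"),
            observed=pres.percent_variance[: cfg.pca_components],
            n_components=cfg.pca_components,
        )
        contrib["random_mean"] = np.nan
        contrib.loc[: f"PC{cfg.pca_components}", "random_mean"] = (
            par.summary["mean"].to_numpy()[: cfg.pca_components])
        _write_csv(contrib, out / "pca_contributions.csv", h, index_label="component")
        geo = geographic_distance_matrix([p for p in populations
                                          if p.name in norm.index]).align_to(list(norm.index))
        pc_d = pc_score_distances(pres, k=cfg.pca_components)
        mres = mantel(pc_d, geo, permutations=cfg.permutations,
                      seed=_stage_seed(cfg.seed, "pca_mantel"))
        _write_csv(pd.DataFrame([{"r": mres.r, "p": mres.p_value,
                                  "permutations": mres.permutations}]),
                   out / "pca_geo_mantel.csv", h, index=False)
        record(stage, {"pca_scores": out / "pca_scores.csv",
                       "pca_contributions": out / "pca_contributions.csv",
                       "pca_geo_mantel": out / "pca_geo_mantel.csv"})
        results["pca"] = pres
        results["parallel"] = par
        results["pca_geo_mantel"] = mres

        # ------------------------------------------------ admixture
        stage = "admixture"
        adm_results: dict[int, list] = {}
        for K in cfg.admixture_K:
            acfg = adm.AdmixtureConfig(
                K=K, burn_in=cfg.admixture_burn_in, run_length=cfg.admixture_run_length,
                runs=cfg.admixture_runs, seed=_stage_seed(cfg.seed, f"adm_{K}"),
            )
            runs = adm.align_runs(adm.fit_admixture_runs(full_loci, acfg))
            adm_results[K] = runs
            best = max(runs, key=lambda r: r.lnP)
            best.write_q(out / f"qmatrix_K{K}.txt")
            _write_csv(best.mean_membership, out / f"mean_membership_K{K}.csv", h,
                       index_label="population")
            products[f"qmatrix_K{K}"] = str(out / f"qmatrix_K{K}.txt")
        chosen, summary = adm.select_K(adm_results)
        _write_csv(summary, out / "admixture_lnP.csv", h, index=False)
        record(stage, {"admixture_lnP": out / "admixture_lnP.csv"})
        results["admixture"] = adm_results
        results["chosen_K"] = chosen

        # ------------------------------------------------ GEN/GEO/LING Mantel table
        stage = "mantel_table"
        pops_fl = dist[("DA", "full_loci")].labels
        geo_m = geographic_distance_matrix(
            [p for p in populations if p.name in pops_fl]).align_to(pops_fl)
        ling_m = linguistic_distance_matrix(tree, pops_fl)
        groups = {p: tree.leaf_of(p) for p in pops_fl}
        table3 = exclusion_analysis(
            {"GEN": dist[("DA", "full_loci")], "GEO": geo_m, "LING": ling_m},
            groups, permutations=cfg.permutations, seed=_stage_seed(cfg.seed, stage),
        )
        _write_csv(table3, out / "mantel_table.csv", h, index=False)
        ling_m.to_phylip(out / "dist_linguistic.phy")
        geo_m.to_phylip(out / "dist_geographic.phy")
        record(stage, {"mantel_table": out / "mantel_table.csv",
                       "dist_linguistic": out / "dist_linguistic.phy",
                       "dist_geographic": out / "dist_geographic.phy"})
        results["mantel_table"] = table3
        log.info("full analysis finished in %.1f s", time.time() - t0)
    except Exception as exc:
        manifest["failed"] = {"stage": stage, "error": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    products["manifest"] = str(out / "manifest.json")
    return results
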