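"""End-to-end orchestration: map -> filter -> associate -> heterogeneity ->
re-associate -> GSEA + ARTP -> normalize/FDR -> joint report.

Every stage is a pure function of (inputs, configuration, seed), so a rerun
with the same seed is byte-identical.  The per-SNP score scan — observed and
permuted — is computed once; because removing heterogeneous SNPs changes
only which SNPs feed each gene's minimum (not any SNP's p-value), both the
pre-filter and post-filter pathway analyses consume the same scan and the
same permutation replicates, which keeps the two reports comparable (the
joint report carries the pre-filter values in companion columns).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pathgwas import annotation as ann
from pathgwas import artp as artp_mod
from pathgwas import association as assoc
from pathgwas import gsea as gsea_mod
from pathgwas import heterogeneity as het
from pathgwas import io as pio
from pathgwas import significance as sig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str
    samples: str
    snps: str
    genes: str
    gmt: str
    out: str
    upstream: int = 20_000
    downstream: int = 10_000
    min_genes: int = 5
    max_genes: int = 100
    maf_min: float = 0.01
    b_permutations: int = 10_000
    seed: int = 0
    het_threshold: float = 0.2
    covariates: list[str] = field(default_factory=lambda: list(assoc.DEFAULT_COVARIATES))
    pooling: bool = False
    overlap_denominator: str = "min"
    weight_p: float = 1.0
    wald_table: bool = True

    def __post_init__(self) -> None:
        for attr in ("genotypes", "samples", "snps", "genes", "gmt"):
            path = Path(getattr(self, attr))
            if not path.exists():
                raise FileNotFoundError(f"{attr} file not found: {path}")
        if self.b_permutations < 1:
            raise ValueError("b_permutations must be >= 1")
        for name in ("maf_min", "het_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StateResult:
    """Pathway results for one dataset state (pre- or post-filter)."""

    gene_results: list[assoc.GeneResult]
    gsea: list[gsea_mod.GseaResult]
    artp: list[artp_mod.ArtpResult]
    report: pd.DataFrame  # set_id, n_genes_with_data, es/nes, p/fdr per method


@dataclass
class PipelineResult:
    out: Path
    db: ann.PathwayDB
    smap_pre: ann.SnpGeneMap
    smap_post: ann.SnpGeneMap
    removed_snps: list[str]
    pre: StateResult
    post: StateResult
    report: pd.DataFrame


def _pathway_state(
    db: ann.PathwayDB,
    smap: ann.SnpGeneMap,
    snp_ids: list[str],
    obs_p: np.ndarray,
    perm_p: np.ndarray,
    weight_p: float,
) -> StateResult:
    genes, obs_gene = assoc.gene_p_matrix(smap, snp_ids, obs_p[None, :])
    _, perm_gene = assoc.gene_p_matrix(smap, snp_ids, perm_p)
    obs_gene = obs_gene[0]
    p_by_snp = dict(zip(snp_ids, obs_p))
    gene_results = assoc.best_snp_per_gene(smap, p_by_snp)

    gsea_res, perm_es = gsea_mod.gsea_all(genes, obs_gene, perm_gene, db, weight_p)
    artp_res = artp_mod.artp_all(genes, obs_gene, perm_gene, db)

    # normalization + FDR per method
    rows = {}
    if gsea_res:
        obs_es = np.array([r.es for r in gsea_res])
        ns_obs, ns_perm, keep = sig.normalize_matrix(obs_es, perm_es)
        fdr_vals = np.full(len(gsea_res), np.nan)
        if keep.any():
            fdr_vals[keep] = sig.fdr(ns_obs[keep], ns_perm[:, keep])
        for j, r in enumerate(gsea_res):
            rows[r.set_id] = {
                "n_genes_with_data_gsea": r.n_hit,
                "es": r.es,
                "nes": ns_obs[j] if keep[j] else np.nan,
                "p_gsea": r.p_perm,
                "p_gsea_display": r.p_display,
                "fdr_gsea": fdr_vals[j],
            }
    if artp_res:
        obs_stat = sig.artp_stat_for_normalization(
            np.array([r.min_p for r in artp_res])
        )
        perm_stat = sig.artp_stat_for_normalization(
            np.column_stack([r.perm_min_p for r in artp_res])
        )
        ns_obs, ns_perm, keep = sig.normalize_matrix(obs_stat, perm_stat)
        fdr_vals = np.full(len(artp_res), np.nan)
        if keep.any():
            fdr_vals[keep] = sig.fdr(ns_obs[keep], ns_perm[:, keep])
        for j, r in enumerate(artp_res):
            row = rows.setdefault(r.set_id, {})
            row.update(
                {
                    "n_genes_with_data_artp": r.n_genes,
                    "k_star": r.k_star,
                    "minp": r.min_p,
                    "ns_artp": ns_obs[j] if keep[j] else np.nan,
                    "p_artp": r.p_artp,
                    "fdr_artp": fdr_vals[j],
                }
            )
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "set_id"
    report = report.reset_index()
    return StateResult(gene_results, gsea_res, artp_res, report)


def run_all(config: RunConfig) -> PipelineResult:
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("load inputs")
        genotypes = pio.read_genotypes(config.genotypes)
        samples = pio.read_samples(config.samples)
        snp_table = pio.read_snp_table(config.snps)
        genes = pio.read_gene_bed(config.genes)

        stage("pathway database")
        db = ann.load_gene_sets(config.gmt)
        db = ann.filter_pathways(db, config.min_genes, config.max_genes)
        db = ann.restrict_to_genes(db, {g.gene_id for g in genes})

        stage("SNP-to-gene mapping")
        pw_genes = db.all_genes()
        gene_models = [g for g in genes if g.gene_id in pw_genes]
        known_snps = set(genotypes.snps)
        snp_table = snp_table[snp_table["snp_id"].isin(known_snps)]
        smap = ann.map_snps_to_genes(
            snp_table, gene_models, config.upstream, config.downstream
        )
        units = None
        if config.pooling:
            units = ann.pool_shared_loci(smap)
            logger.info("pooled %d genes into %d locus units",
                        len(smap.gene_to_snps), len(units))
            smap = ann.unit_map(smap, units)
            db = ann.PathwayDB(
                {
                    pw.set_id: ann.Pathway(
                        pw.set_id, pw.source, ann.pathway_genes_as_units(pw, units)
                    )
                    for pw in db
                }
            )
            ann.units_report(units).to_csv(out / "locus_units.tsv", sep="\t", index=False)

        stage("control-MAF filter")
        kept, mafs = assoc.maf_filter(genotypes, samples, config.maf_min)
        mapped = [s for s in kept if s in smap.snp_to_genes]
        logger.info(
            "%d SNPs pass MAF >= %g; %d map to pathway genes",
            len(kept), config.maf_min, len(mapped),
        )
        if not mapped:
            raise RuntimeError("no SNP both passes the MAF filter and maps to a gene")
        sub = genotypes.subset_snps(mapped)

        stage("association scan (observed + permutations)")
        obs_p = assoc.score_scan(sub, samples, config.covariates)
        perms = gsea_mod.make_permutations(
            genotypes.n_samples, config.b_permutations, config.seed
        )
        perm_p = assoc.score_scan(sub, samples, config.covariates, permutations=perms)

        if config.wald_table:
            stage("per-SNP Wald table")
            results = [
                assoc.trend_test(sub.column(s), samples, config.covariates, snp_id=s)
                for s in mapped
            ]
            assoc.snp_results_table(results).to_csv(
                out / "snp_results.tsv", sep="\t", index=False
            )

        stage("pre-filter pathway analysis")
        pre = _pathway_state(db, smap, mapped, obs_p, perm_p, config.weight_p)

        stage("heterogeneity meta-analysis")
        meta = het.meta_all(sub, samples, mapped)
        removed, smap_post = het.flag_and_filter(meta, smap, config.het_threshold)
        het.meta_table(meta, set(removed)).to_csv(
            out / "heterogeneity.tsv", sep="\t", index=False
        )
        (out / "removed_snps.txt").write_text("".join(s + "\n" for s in removed))

        stage("post-filter pathway analysis")
        post = _pathway_state(db, smap_post, mapped, obs_p, perm_p, config.weight_p)

        stage("reports")
        _write_gene_table(pre, mafs, out / "gene_results_prefilter.tsv")
        _write_gene_table(post, mafs, out / "gene_results.tsv")
        report = _joint_report(db, pre, post)
        report.to_csv(out / "pathway_report.tsv", sep="\t", index=False)

        manifest = {
            "seed": config.seed,
            "b_permutations": config.b_permutations,
            "maf_min": config.maf_min,
            "het_threshold": config.het_threshold,
            "upstream": config.upstream,
            "downstream": config.downstream,
            "pathway_size_bounds": [config.min_genes, config.max_genes],
            "pooling": config.pooling,
            "covariates": config.covariates,
            "weight_p": config.weight_p,
            "n_samples": genotypes.n_samples,
            "n_snps_input": genotypes.n_snps,
            "n_snps_maf_pass": len(kept),
            "n_snps_mapped": len(mapped),
            "n_snps_removed_heterogeneous": len(removed),
            "n_pathways": len(db),
            "n_genes_mapped_pre": len(smap.gene_to_snps),
            "n_genes_mapped_post": len(smap_post.gene_to_snps),
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    return PipelineResult(out, db, smap, smap_post, removed, pre, post, report)


def _write_gene_table(state: StateResult, mafs: dict[str, float], path: Path) -> None:
    rows = [
        {
            "gene": g.gene_id,
            "n_snps": g.n_snps,
            "best_snp": g.best_snp_id,
            "snp_rank": g.snp_rank,
            "maf": mafs.get(g.best_snp_id, np.nan),
            "p": g.p_j,
            "r": g.r_j,
        }
        for g in state.gene_results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _joint_report(
    db: ann.PathwayDB, pre: StateResult, post: StateResult
) -> pd.DataFrame:
    """Joint table: post-filter values with pre-filter companions.

    Mirrors the published convention of printing the pre-filter result in
    parentheses next to the post-filter one.
    """
    pre_r = pre.report.set_index("set_id")
    post_r = post.report.set_index("set_id")
    rows = []
    for pw in db:
        sid = pw.set_id
        row = {"set_id": sid, "source": pw.source, "n_genes": pw.size}
        for col in (
            "n_genes_with_data_gsea", "es", "nes", "p_gsea", "fdr_gsea",
            "n_genes_with_data_artp", "k_star", "minp", "p_artp", "fdr_artp",
        ):
            row[col] = post_r[col].get(sid, np.nan) if col in post_r else np.nan
            pre_col = f"{col}_prefilter"
            row[pre_col] = pre_r[col].get(sid, np.nan) if col in pre_r else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
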