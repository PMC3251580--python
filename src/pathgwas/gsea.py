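"""Weighted Kolmogorov-Smirnov gene-set enrichment over ranked gene statistics.

Genes are ranked by ``r_j = -log10(best-SNP p)`` descending.  Walking down
the list, the running sum gains ``r_j^p / N_R`` at pathway members (``N_R``
the sum of member weights) and loses ``1/(N - N_H)`` at non-members; the
enrichment score ``ES`` is the maximum of the running sum — an enrichment-
only (positive-deviation) statistic measuring how strongly the pathway's
genes concentrate near the top of the ranking.

Significance is empirical: whole genotype rows are reassigned to individuals
(one global shuffle per replicate, preserving LD between SNPs and the
phenotype-covariate relationship), the per-SNP tests and best-SNP gene
statistics recomputed, and ES re-evaluated.  The same permutation replicates
serve every pathway, and the same gene-level permutation p-value matrix is
shared with the rank-truncated-product statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathgwas import association
from pathgwas.annotation import PathwayDB, SnpGeneMap
from pathgwas.io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GseaResult:
    set_id: str
    es: float
    n_total: int      # N: genes analyzed genome-wide
    n_hit: int        # N_H: pathway genes with data
    weight_p: float
    p_perm: float
    b: int

    @property
    def p_display(self) -> str:
        """Zero exceedance counts are reported as '<1/B'."""
        return f"<{1.0 / self.b:g}" if self.p_perm == 0 else f"{self.p_perm:g}"


def rank_genes(gene_ids: list[str], r: np.ndarray) -> np.ndarray:
    """Order (descending r) with deterministic id tie-break; returns indices."""
    ids = np.asarray(gene_ids)
    return np.lexsort((ids, -np.asarray(r, float)))


def enrichment_score(
    gene_ids: list[str],
    r: np.ndarray,
    member_genes: set[str],
    weight_p: float = 1.0,
) -> float:
    """ES for one gene set against the full ranked gene list.

    ``gene_ids``/``r`` cover every analyzed gene (any order); membership is
    by gene id.  Undefined when the set covers no gene or every gene.
    """
    r = np.asarray(r, dtype=float)
    n = len(gene_ids)
    hit = np.fromiter((g in member_genes for g in gene_ids), bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError(f"ES undefined: N_H={n_hit} of N={n}")
    order = rank_genes(gene_ids, r)
    hit_o = hit[order]
    w = np.abs(r[order]) ** weight_p
    n_r = math.fsum(w[hit_o])  # exactly rounded, summation-order independent
    if n_r == 0:
        logger.warning("all member weights zero; ES at its defined limit")
        return -n_hit / (n - n_hit)
    inc = np.where(hit_o, w / n_r, -1.0 / (n - n_hit))
    # strict left-to-right accumulation (SIMD cumsum can differ by 1 ulp)
    running, best = 0.0, -np.inf
    for step in inc:
        running += step
        best = max(best, running)
    return float(best)


def gsea_pvalue(obs_es: float, perm_es: np.ndarray) -> float:
    """Empirical p: fraction of permutation ES >= observed (ties count)."""
    perm_es = np.asarray(perm_es, float)
    if perm_es.size == 0:
        raise ValueError("empty permutation sample")
    return float(np.count_nonzero(perm_es >= obs_es) / perm_es.size)


def make_permutations(n_samples: int, b: int, seed: int) -> np.ndarray:
    """B global row-shuffles, one per replicate, from a single seeded PRNG."""
    if b < 1:
        raise ValueError("permutation count B must be >= 1")
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(n_samples) for _ in range(b)])


def gene_level_null(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    smap: SnpGeneMap,
    b: int = 10_000,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Observed and permuted best-SNP gene p-values under one shared null.

    Returns ``(gene_ids, obs_p (N,), perm_p (B, N))``.  The permutation
    replicates are identical for every pathway and are the single null pool
    consumed by both enrichment methods and by the FDR normalization.
    """
    snp_ids = [s for s in genotypes.snps if s in smap.snp_to_genes]
    sub = genotypes.subset_snps(snp_ids)
    obs = association.score_scan(sub, samples, covariates)
    perms = make_permutations(genotypes.n_samples, b, seed)
    perm = association.score_scan(sub, samples, covariates, permutations=perms)
    genes, obs_gene = association.gene_p_matrix(smap, snp_ids, obs[None, :])
    genes2, perm_gene = association.gene_p_matrix(smap, snp_ids, perm)
    assert genes == genes2
    return genes, obs_gene[0], perm_gene


def _es_matrix(
    gene_ids: list[str],
    p_rows: np.ndarray,
    membership: np.ndarray,
    weight_p: float,
) -> np.ndarray:
    """ES for each row of a (B x N) gene p-value matrix x each pathway.

    ``membership`` is a (M x N) boolean matrix.  Vectorized row-wise version
    of :func:`enrichment_score` (same increments, same cumulative order).
    """
    ids = np.asarray(gene_ids)
    B, n = p_rows.shape
    m = membership.shape[0]
    n_hit = membership.sum(axis=1)
    out = np.empty((B, m))
    with np.errstate(divide="ignore"):
        r_all = -np.log10(p_rows)
    for b_i in range(B):
        r = r_all[b_i]
        order = np.lexsort((ids, -r))
        w = np.abs(r[order]) ** weight_p
        hit_s = membership[:, order]                      # (M, N)
        n_r = np.where(hit_s, w[None, :], 0.0).sum(axis=1)  # (M,)
        safe_nr = np.where(n_r > 0, n_r, 1.0)
        miss_dec = 1.0 / (n - n_hit)
        inc = np.where(hit_s, w[None, :] / safe_nr[:, None], -miss_dec[:, None])
        es = np.cumsum(inc, axis=1).max(axis=1)
        es = np.where(n_r > 0, es, -n_hit / (n - n_hit))
        out[b_i] = es
    return out


def gsea_all(
    gene_ids: list[str],
    obs_gene_p: np.ndarray,
    perm_gene_p: np.ndarray,
    db: PathwayDB,
    weight_p: float = 1.0,
) -> tuple[list[GseaResult], np.ndarray]:
    """Observed ES, permutation ES, and empirical p per pathway.

    Pathways covering no analyzed gene or all of them are skipped with a
    warning.  Returns the result list plus the (B x M) permutation ES matrix
    (columns aligned with the result list) for downstream normalization.
    """
    idx = {g: j for j, g in enumerate(gene_ids)}
    n = len(gene_ids)
    kept, rows = [], []
    for pw in db:
        cols = [idx[g] for g in pw.genes if g in idx]
        if not (0 < len(cols) < n):
            logger.warning("%s skipped: N_H=%d of N=%d", pw.set_id, len(cols), n)
            continue
        mask = np.zeros(n, bool)
        mask[cols] = True
        kept.append(pw)
        rows.append(mask)
    if not kept:
        return [], np.empty((perm_gene_p.shape[0], 0))
    membership = np.stack(rows)
    obs_es = _es_matrix(gene_ids, obs_gene_p[None, :], membership, weight_p)[0]
    perm_es = _es_matrix(gene_ids, perm_gene_p, membership, weight_p)
    b = perm_gene_p.shape[0]
    results = [
        GseaResult(
            set_id=pw.set_id,
            es=float(obs_es[j]),
            n_total=n,
            n_hit=int(membership[j].sum()),
            weight_p=weight_p,
            p_perm=gsea_pvalue(obs_es[j], perm_es[:, j]),
            b=b,
        )
        for j, pw in enumerate(kept)
    ]
    return results, perm_es
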