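"""Per-SNP covariate-adjusted trend tests and best-SNP gene statistics.

Two routes to the 1-df additive trend test are provided:

* :func:`trend_test` — a full maximum-likelihood logistic fit per SNP
  (``status ~ dosage + covariates``) returning Wald per-allele statistics
  (log-OR, SE, 95% CI, p).  Used for reporting per-SNP effect sizes.
  A likelihood-ratio p-value is available behind ``lrt=True``.
* :func:`score_scan` — the efficient-score version of the same 1-df test,
  with the covariate-only null model fitted once.  Because the null fit does
  not involve the genotype, the scan vectorizes over all SNPs and over
  genotype-row permutations as dense matrix products, which is what makes a
  shared permutation null with thousands of refits feasible.  Score and Wald
  tests are asymptotically equivalent.

Gene-level evidence is the minimum p-value over the SNPs mapped to the
gene's region (or pooled locus unit), carried as ``r_j = -log10(p_j)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pathgwas.annotation import SnpGeneMap
from pathgwas.io import SMOKING_LEVELS, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", "study", "dna_source", "smoking"]


@dataclass
class SnpResult:
    """Per-allele Wald statistics for one SNP."""

    snp_id: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p_trend: float
    maf_controls: float
    n_used: int
    ok: bool = True
    reason: str = ""


@dataclass
class GeneResult:
    """A gene (or pooled locus unit) summarized by its best SNP."""

    gene_id: str
    best_snp_id: str
    p_j: float
    r_j: float
    snp_rank: int = 1
    n_snps: int = 1


def build_design(
    samples: pd.DataFrame, covariates: list[str] | None = None
) -> np.ndarray:
    """Covariate design matrix with intercept.

    Categorical covariates enter as indicator contrasts: smoking uses
    ``never`` as reference; study uses its first (sorted) level as reference;
    ``sex`` and ``dna_source`` are already 0/1; ``age`` is numeric.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    cols = [np.ones(len(samples))]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} not in sample table")
        if samples[cov].isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        if cov == "smoking":
            for level in SMOKING_LEVELS[1:]:
                cols.append((samples[cov] == level).to_numpy(float))
        elif cov == "study":
            levels = sorted(samples[cov].unique())
            for level in levels[1:]:
                cols.append((samples[cov] == level).to_numpy(float))
        else:
            cols.append(samples[cov].to_numpy(float))
    return np.column_stack(cols)


def control_maf(genotypes: GenotypeMatrix, samples: pd.DataFrame, snp_id: str) -> float:
    """Minor-allele frequency among controls, complete-case, folded to <=0.5.

    Returns ``nan`` when every control genotype is missing (the SNP is then
    excluded upstream).
    """
    g = genotypes.column(snp_id)
    ctrl = samples["status"].to_numpy() == 0
    gc = g[ctrl]
    gc = gc[~np.isnan(gc)]
    if gc.size == 0:
        logger.warning("%s: all control genotypes missing; MAF undefined", snp_id)
        return float("nan")
    freq = gc.sum() / (2 * gc.size)
    return float(min(freq, 1.0 - freq))


def maf_filter(
    genotypes: GenotypeMatrix, samples: pd.DataFrame, threshold: float = 0.01
) -> tuple[list[str], dict[str, float]]:
    """Retain SNPs with control MAF >= threshold (strict ``<`` excludes).

    Returns the retained SNP ids and a snp_id -> control MAF dict for all
    SNPs with a defined MAF.
    """
    ctrl = samples["status"].to_numpy() == 0
    G = genotypes.dosages[ctrl]
    n_obs = np.sum(~np.isnan(G), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(G, axis=0) / (2 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    kept, mafs = [], {}
    for i, snp in enumerate(genotypes.snps):
        if n_obs[i] == 0:
            logger.warning("%s: no control genotypes; excluded", snp)
            continue
        mafs[snp] = float(maf[i])
        if maf[i] >= threshold:
            kept.append(snp)
    return kept, mafs


def trend_test(
    genotype_vector: np.ndarray,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    snp_id: str = "",
    lrt: bool = False,
) -> SnpResult:
    """Wald (or LRT) per-allele test from a per-SNP ML logistic fit.

    Missing genotypes are handled complete-case.  Separation or
    non-convergence yields a flagged result (``ok=False``) that the gene
    statistics exclude; a constant dosage vector is likewise flagged.
    """
    g = np.asarray(genotype_vector, dtype=float)
    keep = ~np.isnan(g)
    g = g[keep]
    sub = samples.loc[keep]
    y = sub["status"].to_numpy(float)
    maf = control_maf_vector(g, sub)
    n = int(keep.sum())

    def flagged(reason: str) -> SnpResult:
        logger.info("%s excluded from gene statistics: %s", snp_id or "<snp>", reason)
        return SnpResult(snp_id, np.nan, np.nan, np.nan, (np.nan, np.nan),
                         np.nan, maf, n, ok=False, reason=reason)

    if y.min() == y.max():
        return flagged("no cases or no controls among complete cases")
    if g.min() == g.max():
        return flagged("constant dosage")

    X = np.column_stack([g, build_design(sub, covariates)])
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        return flagged(f"fit failed: {exc}")
    if not fit.converged:
        return flagged("non-convergence")
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not np.isfinite(se) or se > 50 or abs(beta) > 20:
        return flagged("quasi-separation (unstable estimate)")
    if lrt:
        with np.errstate(all="ignore"):
            fit0 = sm.GLM(y, X[:, 1:], family=sm.families.Binomial()).fit(maxiter=100)
        lr = 2.0 * (fit.llf - fit0.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), 1))
    else:
        p = float(stats.chi2.sf((beta / se) ** 2, 1))
    p = max(p, np.nextafter(0, 1))  # p in (0, 1]
    return SnpResult(
        snp_id=snp_id,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        p_trend=p,
        maf_controls=maf,
        n_used=n,
    )


def control_maf_vector(g: np.ndarray, samples: pd.DataFrame) -> float:
    ctrl = samples["status"].to_numpy() == 0
    gc = g[ctrl]
    gc = gc[~np.isnan(gc)]
    if gc.size == 0:
        return float("nan")
    f = gc.sum() / (2 * gc.size)
    return float(min(f, 1 - f))


def snp_results_table(results: list[SnpResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "or": [r.or_ for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p_trend": [r.p_trend for r in results],
            "maf_controls": [r.maf_controls for r in results],
            "n_used": [r.n_used for r in results],
            "ok": [r.ok for r in results],
            "reason": [r.reason for r in results],
        }
    )


# ---------------------------------------------------------------------------
# vectorized score scan (shared by the permutation engine)
# ---------------------------------------------------------------------------


def _null_fit(samples: pd.DataFrame, covariates: list[str] | None):
    X = build_design(samples, covariates)
    y = samples["status"].to_numpy(float)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    mu = np.asarray(fit.fittedvalues)
    w = mu * (1.0 - mu)
    return X, y, mu, w


def score_scan(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    permutations: np.ndarray | None = None,
) -> np.ndarray:
    """1-df score-test p-values for every SNP, optionally under permutations.

    The covariate-only null logistic model is fitted once.  For SNP dosage
    vector g the score statistic is ``U = g'(y - mu)`` with variance
    ``V = g'Wg - g'WX (X'WX)^-1 X'Wg`` and p from chi-square(1) of ``U^2/V``.

    Permuting whole genotype rows against fixed (phenotype, covariates) is
    algebraically identical to permuting the residual/weight/design rows
    against fixed genotypes, so ``permutations`` is an integer array of shape
    (B, n_samples); row b gives the sample-index permutation for replicate b.
    Returns p-values of shape (n_snps,) or (B, n_snps).  Missing dosages are
    mean-imputed per SNP (see module docstring of :mod:`pathgwas.pipeline`).
    """
    X, y, mu, w = _null_fit(samples, covariates)
    G = genotypes.dosages
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    r = y - mu

    # X'WX is invariant under joint row permutation of (X, w)
    XtWX = X.T @ (w[:, None] * X)
    A = np.linalg.inv(XtWX)
    G2 = G * G

    def _stats(r_p: np.ndarray, w_p: np.ndarray, X_p: np.ndarray) -> np.ndarray:
        U = G.T @ r_p                      # (m,)
        gWg = G2.T @ w_p                   # (m,)
        C = G.T @ (w_p[:, None] * X_p)     # (m, c)
        V = gWg - np.einsum("mc,cd,md->m", C, A, C)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(V > 0, U * U / np.maximum(V, 1e-300), 0.0)
        p = stats.chi2.sf(chi2, 1)
        return np.clip(p, np.nextafter(0, 1), 1.0)

    if permutations is None:
        return _stats(r, w, X)

    B = permutations.shape[0]
    out = np.empty((B, genotypes.n_snps))
    for b in range(B):
        perm = permutations[b]
        out[b] = _stats(r[perm], w[perm], X[perm])
    return out


# ---------------------------------------------------------------------------
# gene-level reduction
# ---------------------------------------------------------------------------


def best_snp_per_gene(
    smap: SnpGeneMap, p_by_snp: dict[str, float]
) -> list[GeneResult]:
    """Represent each gene/locus unit by its minimum-p SNP.

    SNPs absent from ``p_by_snp`` (MAF-filtered, failed fits, heterogeneity-
    removed) are ignored; genes with no retained SNP are dropped and counted.
    Ties on p break to the lexicographically smaller snp_id.
    """
    out = []
    dropped = 0
    for gene in sorted(smap.gene_to_snps):
        snps = [s for s in smap.gene_to_snps[gene] if s in p_by_snp]
        if not snps:
            dropped += 1
            continue
        snps_sorted = sorted(snps)  # lexicographic tie-break
        ps = np.array([p_by_snp[s] for s in snps_sorted])
        i = int(np.argmin(ps))  # first minimum -> smallest snp_id on ties
        p_j = float(ps[i])
        rank = int(stats.rankdata(ps, method="min")[i])
        out.append(
            GeneResult(
                gene_id=gene,
                best_snp_id=snps_sorted[i],
                p_j=p_j,
                r_j=float(-np.log10(p_j)),
                snp_rank=rank,
                n_snps=len(snps_sorted),
            )
        )
    if dropped:
        logger.info("%d gene(s) had no retained SNP and were dropped", dropped)
    return out


def gene_p_matrix(
    smap: SnpGeneMap,
    snp_ids: list[str],
    p_matrix: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    """Reduce a (B x n_snps) SNP p-value matrix to gene-level minima.

    ``snp_ids`` gives the column order of ``p_matrix``.  Returns the sorted
    gene ids with >=1 retained SNP and the (B x n_genes) matrix of per-gene
    minimum p-values.  Used to build the shared permutation null consumed by
    both enrichment methods.
    """
    col = {s: j for j, s in enumerate(snp_ids)}
    genes = []
    mats = []
    P = np.atleast_2d(p_matrix)
    for gene in sorted(smap.gene_to_snps):
        idx = [col[s] for s in smap.gene_to_snps[gene] if s in col]
        if not idx:
            continue
        genes.append(gene)
        mats.append(P[:, idx].min(axis=1))
    if not genes:
        return [], np.empty((P.shape[0], 0))
    return genes, np.column_stack(mats)
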