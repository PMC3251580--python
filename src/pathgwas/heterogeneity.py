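"""Cross-study heterogeneity screen: per-SNP meta-analysis, Cochran's Q, I2.

A pooled multi-study case-control analysis can be driven by a SNP whose
effect differs wildly between studies — often an artifact (batch,
population) rather than a reproducible signal.  For each SNP, a per-allele
odds ratio is estimated within each study from the 2x2 allele-count table
(allele counts = genotype-weighted counts, i.e. twice the sample count
weighted by dosage), the study estimates are combined by inverse-variance
fixed-effect meta-analysis, and heterogeneity is quantified by Cochran's Q
with ``I2 = max(0, 100*(Q - df)/Q)`` — the percentage of total variation in
study estimates attributable to heterogeneity.  SNPs whose Q p-value falls
below the threshold (default 0.2) are removed from every gene before the
pathway analysis is re-run; reports carry both pre- and post-filter results.

A per-study logistic (genotype-based) effect estimate is available behind
``method="logistic"``; estimates are typically similar to the allele-count
route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathgwas.annotation import SnpGeneMap
from pathgwas.io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class StudyEffect:
    study_id: str
    log_or: float
    se: float


@dataclass
class MetaResult:
    snp_id: str
    pooled_log_or: float
    pooled_se: float
    q: float
    df: int
    q_p: float
    i2: float
    n_studies: int


def per_study_effect(
    a: float, b: float, c: float, d: float, study_id: str = ""
) -> StudyEffect | None:
    """Log OR and SE from a 2x2 allele-count table.

    ``a/b`` = effect/reference allele counts in cases, ``c/d`` in controls.
    Adds 0.5 to every cell when any cell is zero (Haldane-Anscombe).
    Returns None (study dropped) when a whole margin is zero.
    """
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        logger.info("study %s dropped: empty margin in allele table", study_id)
        return None
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return StudyEffect(study_id, log_or, se)


def allele_tables(
    g: np.ndarray, status: np.ndarray, study: np.ndarray
) -> dict[str, tuple[float, float, float, float]]:
    """Per-study 2x2 allele-count tables for one SNP (complete-case).

    The counted allele is the dosage allele; each sample contributes two
    alleles, ``g`` of them the counted one.
    """
    out = {}
    obs = ~np.isnan(g)
    for st in sorted(pd.unique(study)):
        m = obs & (study == st)
        cases = m & (status == 1)
        ctrls = m & (status == 0)
        a = float(np.sum(g[cases]))
        b = float(2 * cases.sum() - a)
        c = float(np.sum(g[ctrls]))
        d = float(2 * ctrls.sum() - c)
        out[st] = (a, b, c, d)
    return out


def _logistic_study_effect(
    g: np.ndarray, status: np.ndarray, mask: np.ndarray, study_id: str
) -> StudyEffect | None:
    import statsmodels.api as sm

    gm, ym = g[mask], status[mask]
    if gm.size == 0 or ym.min() == ym.max() or gm.min() == gm.max():
        return None
    X = np.column_stack([gm, np.ones(gm.size)])
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(ym.astype(float), X, family=sm.families.Binomial()).fit()
    except Exception:
        return None
    if not fit.converged or not np.isfinite(fit.bse[0]) or fit.bse[0] > 50:
        return None
    return StudyEffect(study_id, float(fit.params[0]), float(fit.bse[0]))


def cochran_q(effects: list[StudyEffect], snp_id: str = "") -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q and I2.

    With a single study Q is undefined; by convention the SNP then passes the
    filter (q_p = 1, I2 = 0) with a log message.
    """
    if not effects:
        raise ValueError(f"{snp_id}: no study effects")
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    k = len(effects)
    if k == 1:
        logger.info("%s: single study, Q undefined; passes filter", snp_id)
        return MetaResult(snp_id, pooled, pooled_se, np.nan, 0, 1.0, 0.0, 1)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= df else float(100.0 * (q - df) / q)
    return MetaResult(snp_id, pooled, pooled_se, q, df, max(q_p, np.nextafter(0, 1)), i2, k)


def meta_all(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    snp_ids: list[str] | None = None,
    method: str = "allele",
) -> list[MetaResult]:
    """Per-SNP meta-analysis across studies for the given SNPs."""
    if method not in ("allele", "logistic"):
        raise ValueError(f"unknown method {method!r}")
    status = samples["status"].to_numpy()
    study = samples["study"].to_numpy()
    out = []
    for snp in snp_ids if snp_ids is not None else genotypes.snps:
        g = genotypes.column(snp)
        effects: list[StudyEffect] = []
        if method == "allele":
            for st, (a, b, c, d) in allele_tables(g, status, study).items():
                eff = per_study_effect(a, b, c, d, study_id=st)
                if eff is not None:
                    effects.append(eff)
        else:
            obs = ~np.isnan(g)
            for st in sorted(pd.unique(study)):
                eff = _logistic_study_effect(g, status, obs & (study == st), st)
                if eff is not None:
                    effects.append(eff)
        if not effects:
            logger.warning("%s: no usable study; skipped from meta-analysis", snp)
            continue
        out.append(cochran_q(effects, snp_id=snp))
    return out


def meta_table(results: list[MetaResult], removed: set[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "pooled_or": [float(np.exp(r.pooled_log_or)) for r in results],
            "ci_low": [float(np.exp(r.pooled_log_or - 1.96 * r.pooled_se)) for r in results],
            "ci_high": [float(np.exp(r.pooled_log_or + 1.96 * r.pooled_se)) for r in results],
            "q": [r.q for r in results],
            "df": [r.df for r in results],
            "q_p": [r.q_p for r in results],
            "i2": [r.i2 for r in results],
            "removed": [int(r.snp_id in removed) for r in results],
        }
    )


def flag_and_filter(
    results: list[MetaResult], smap: SnpGeneMap, threshold: float = 0.2
) -> tuple[list[str], SnpGeneMap]:
    """Remove SNPs with Q p-value < threshold from every gene's SNP list.

    The removal is global; genes left without SNPs are dropped by
    ``SnpGeneMap.drop_snps`` and downstream gene best-SNP statistics must be
    recomputed on the returned map.
    """
    removed = sorted(r.snp_id for r in results if r.q_p < threshold)
    filtered = smap.drop_snps(set(removed))
    logger.info(
        "heterogeneity filter removed %d of %d SNP(s) at Q-p < %g",
        len(removed), len(results), threshold,
    )
    return removed, filtered
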