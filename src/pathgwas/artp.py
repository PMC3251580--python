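"""Adaptive rank-truncated product (ARTP) pathway statistic.

For a pathway with L gene-level p-values sorted ascending, the candidate
statistics are the truncation products ``W(K) = prod of the K smallest
p-values`` for every K in 1..L.  A two-level permutation procedure turns the
family into a single adjusted p-value:

1. the observed data is treated as replicate 0 of a single exchangeable
   pool of B+1 replicates; each W(K) is converted to an estimated p-value
   ``s_hat_i(K) = #{j in 0..B : W_j(K) <= W_i(K)} / (B+1)`` (ties and self
   counted, so estimates are never 0);
2. the adaptive statistic is ``minP_i = min_K s_hat_i(K)``; the final
   p-value is the rank of the observed minP within the pool,
   ``p = #{i : minP_i <= minP_0} / (B+1)``, which adjusts for the
   minimization over truncation points.  Because the pool is exchangeable
   under the null, p is a valid (slightly conservative) p-value.

All products are carried in log space; comparisons are on log W.  The
permutation pool is the same gene-level null matrix used by the KS
enrichment score, so the two methods are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pathgwas.annotation import PathwayDB

logger = logging.getLogger(__name__)


@dataclass
class ArtpResult:
    set_id: str
    n_genes: int                 # L: genes with data
    k_star: int                  # argmin truncation point (smallest on ties)
    min_p: float                 # min_K s_hat(K), the adaptive statistic
    p_artp: float                # final permutation-adjusted p-value
    b: int
    k_grid: list[int] = field(default_factory=list)
    s_hat: list[float] = field(default_factory=list)
    w_log: list[float] = field(default_factory=list)
    perm_min_p: np.ndarray | None = None  # (B,) replicate minP, for FDR


def truncation_products(p_values: np.ndarray, log: bool = False) -> np.ndarray:
    """W(K) = product of the K smallest p-values, K = 1..L.

    Input need not be sorted; values must lie in (0, 1].  Computed in log
    space; set ``log=True`` to get log W(K) directly.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if p[0] <= 0 or p[-1] > 1:
        raise ValueError("p-values must lie in (0, 1]")
    logw = np.cumsum(np.log(p))
    return logw if log else np.exp(logw)


def _rank_leq(pool_sorted: np.ndarray, values: np.ndarray) -> np.ndarray:
    """#{pool <= v} for each v, ties counted (searchsorted right)."""
    return np.searchsorted(pool_sorted, values, side="right")


def artp_pathway(
    obs_gene_p: np.ndarray,
    perm_gene_p: np.ndarray,
    set_id: str = "",
    k_grid: list[int] | None = None,
) -> ArtpResult:
    """Two-level ARTP for one pathway.

    ``obs_gene_p`` has length L; ``perm_gene_p`` is the (B x L) slice of the
    shared permutation null with columns aligned to the same genes.  The
    truncation grid defaults to every integer 1..L.
    """
    obs = np.asarray(obs_gene_p, float)
    perm = np.atleast_2d(np.asarray(perm_gene_p, float))
    L = obs.size
    if L == 0:
        raise ValueError("pathway has no genes with data")
    B = perm.shape[0]
    if perm.shape[1] != L:
        raise ValueError("permutation matrix column count != number of genes")
    if B < 20:
        logger.warning("%s: B=%d permutations give unstable ARTP estimates", set_id, B)
    if k_grid is None:
        k_grid = list(range(1, L + 1))
    if any(k < 1 or k > L for k in k_grid):
        raise ValueError("truncation points must lie in 1..L")
    ks = np.asarray(sorted(k_grid), int)

    obs_logw = truncation_products(obs, log=True)[ks - 1]          # (K,)
    perm_logw = np.cumsum(np.log(np.sort(perm, axis=1)), axis=1)[:, ks - 1]  # (B, K)

    # one exchangeable pool: observed = replicate 0
    all_logw = np.vstack([obs_logw[None, :], perm_logw])           # (B+1, K)
    s_hat = np.empty_like(all_logw)
    for j in range(len(ks)):
        pool = np.sort(all_logw[:, j])
        s_hat[:, j] = _rank_leq(pool, all_logw[:, j]) / (B + 1)

    min_all = s_hat.min(axis=1)
    min_obs = float(min_all[0])
    j_star = int(np.argmin(s_hat[0]))  # first minimum -> smallest K on ties
    min_perm = min_all[1:]
    p_artp = float(np.count_nonzero(min_all <= min_obs) / (B + 1))

    return ArtpResult(
        set_id=set_id,
        n_genes=L,
        k_star=int(ks[j_star]),
        min_p=min_obs,
        p_artp=p_artp,
        b=B,
        k_grid=ks.tolist(),
        s_hat=s_hat[0].tolist(),
        w_log=obs_logw.tolist(),
        perm_min_p=min_perm,
    )


def artp_all(
    gene_ids: list[str],
    obs_gene_p: np.ndarray,
    perm_gene_p: np.ndarray,
    db: PathwayDB,
    k_grid: list[int] | None = None,
) -> list[ArtpResult]:
    """ARTP per pathway from the shared gene-level null.

    Every pathway is scored against the *same* permutation replicates
    (identical row indices), restricted to its own gene columns.  Pathways
    with no gene with data are skipped with a log message.
    """
    idx = {g: j for j, g in enumerate(gene_ids)}
    out = []
    for pw in db:
        cols = [idx[g] for g in pw.genes if g in idx]
        if not cols:
            logger.warning("%s skipped: no genes with data", pw.set_id)
            continue
        grid = None
        if k_grid is not None:
            grid = [k for k in k_grid if k <= len(cols)] or None
        out.append(
            artp_pathway(
                obs_gene_p[cols], perm_gene_p[:, cols], set_id=pw.set_id, k_grid=grid
            )
        )
    return out
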