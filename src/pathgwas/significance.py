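"""Permutation normalization of pathway statistics and permutation-based FDR.

Pathways differ in size and gene composition, so raw enrichment statistics
are not comparable across pathways.  Each pathway's statistic (observed and
every permutation replicate) is normalized by the mean and standard
deviation of its own permutation distribution, giving NS values on a common
scale where larger means more significant.  The KS enrichment score is
normalized directly; the adaptive rank-truncated-product statistic is
mapped to ``-log(minP)`` first so both methods share orientation.

The FDR at threshold ``s*`` is the ratio of the expected fraction of
permuted NS values exceeding ``s*`` to the observed fraction exceeding it,
clipped to [0, 1] and made monotone (non-increasing in ``s*``) by a
cumulative minimum taken from the least-significant threshold upward, as in
Benjamini-Hochberg-style q-value smoothing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def normalize(observed: float, perm_stats: np.ndarray) -> tuple[float, np.ndarray]:
    """NS = (stat - perm mean) / perm SD, for the observed value and every
    permutation value of one pathway.

    Raises ``ValueError`` when the permutation SD is 0 or fewer than two
    finite replicates exist (the pathway is then excluded from the FDR).
    """
    perm = np.asarray(perm_stats, float)
    perm = perm[np.isfinite(perm)]
    if perm.size < 2:
        raise ValueError("need >=2 finite permutation values to normalize")
    mu = perm.mean()
    sd = perm.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate permutation distribution (SD=0)")
    return float((observed - mu) / sd), (np.asarray(perm_stats, float) - mu) / sd


def normalize_matrix(
    observed: np.ndarray, perm_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pathway normalization of a (B x M) permutation statistic matrix.

    Returns (obs NS (M,), perm NS (B x M), keep mask (M,)); pathways with a
    degenerate permutation distribution are flagged out of the FDR.
    """
    obs = np.asarray(observed, float)
    perm = np.asarray(perm_matrix, float)
    mu = perm.mean(axis=0)
    sd = perm.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "%d pathway(s) excluded from FDR (permutation SD = 0)",
            int((~keep).sum()),
        )
    safe = np.where(keep, sd, 1.0)
    return (obs - mu) / safe, (perm - mu[None, :]) / safe[None, :], keep


def fdr(obs_ns: np.ndarray, perm_ns: np.ndarray) -> np.ndarray:
    """Permutation FDR per pathway, evaluated at each observed NS.

    ``FDR(s*) = [#{perm NS >= s*}/(B*M)] / [#{obs NS >= s*}/M]``, clipped to
    [0, 1], then monotonized so FDR never decreases as the threshold drops.
    Returns the FDR of each pathway at its own NS, aligned with ``obs_ns``.
    """
    obs = np.asarray(obs_ns, float)
    perm = np.asarray(perm_ns, float)
    m = obs.size
    if m == 0:
        return np.empty(0)
    b = perm.shape[0]
    order = np.argsort(-obs, kind="stable")  # descending NS
    pool = np.sort(perm.ravel())
    raw = np.empty(m)
    for rank, i in enumerate(order):
        s = obs[i]
        n_perm_ge = pool.size - np.searchsorted(pool, s, side="left")
        n_obs_ge = np.count_nonzero(obs >= s)
        num = n_perm_ge / (b * m)
        den = n_obs_ge / m
        raw[rank] = min(num / den, 1.0) if den > 0 else 1.0
    # monotone: walk from the least significant threshold toward the most
    # significant, taking the running minimum (BH-style smoothing)
    smooth = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty(m)
    out[order] = smooth
    return out


def fdr_table(
    set_ids: list[str],
    obs_ns: np.ndarray,
    perm_ns: np.ndarray,
    method: str,
) -> pd.DataFrame:
    vals = fdr(obs_ns, perm_ns)
    return pd.DataFrame({"set_id": set_ids, f"ns_{method}": obs_ns, f"fdr_{method}": vals})


def artp_stat_for_normalization(min_p: float | np.ndarray) -> np.ndarray:
    """Map the ARTP adaptive statistic to -log(minP) so larger = more
    significant, matching the ES orientation."""
    return -np.log(np.asarray(min_p, float))
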