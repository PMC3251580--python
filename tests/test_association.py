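import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathgwas import association as assoc
from pathgwas import gsea as gsea_mod
from pathgwas.annotation import SnpGeneMap
from pathgwas.io import GenotypeMatrix


def _samples(status, **extra):
    n = len(status)
    rng = np.random.default_rng(0)
    base = {
        "sample_id": [f"S{i}" for i in range(n)],
        "status": status,
        "age": rng.integers(40, 76, n),
        "sex": rng.integers(0, 2, n),
        "study": "study1",
        "dna_source": rng.integers(0, 2, n),
        "smoking": rng.choice(["never", "former", "occasional", "current"], n),
    }
    base.update(extra)
    return pd.DataFrame(base)


# ---------------------------------------------------------------- control MAF


@pytest.mark.parametrize(
    "dosages,expected",
    [((0, 0, 1, 1), 0.25), ((2, 2, 2, 2), 0.0), ((2, 2, 2, 1), 0.125)],
)
def test_control_maf_arithmetic_and_folding(dosages, expected):
    n = len(dosages)
    gm = GenotypeMatrix([f"S{i}" for i in range(n)], ["s1"],
                        np.array(dosages, float)[:, None])
    samples = _samples(np.zeros(n, int))
    assert assoc.control_maf(gm, samples, "s1") == pytest.approx(expected)


def test_maf_filter_strict_threshold():
    # control MAF exactly 0.01 is retained; just below is excluded
    n = 200
    g_at = np.zeros(n)
    g_at[:4] = 1  # 4/400 = 0.01
    g_below = np.zeros(n)
    g_below[:3] = 1  # 0.0075
    gm = GenotypeMatrix([f"S{i}" for i in range(n)], ["at", "below"],
                        np.column_stack([g_at, g_below]))
    kept, mafs = assoc.maf_filter(gm, _samples(np.zeros(n, int)), 0.01)
    assert kept == ["at"]
    assert mafs["below"] == pytest.approx(0.0075)


# ----------------------------------------------------------------- trend test


def test_null_symmetry_balanced_table():
    """Equal allele counts in cases and controls: OR = 1, p ~ 1."""
    g = np.array([1.0] * 50 + [0.0] * 50 + [1.0] * 50 + [0.0] * 50)
    y = np.array([1] * 100 + [0] * 100)
    r = assoc.trend_test(g, _samples(y), covariates=[])
    assert r.or_ == pytest.approx(1.0, abs=1e-9)
    assert r.p_trend == pytest.approx(1.0, abs=1e-6)


def _newton_2x3(g, y, tol=1e-12):
    """Independent Newton solver for logit(P(case)) = a + b*g on the
    collapsed 2x3 genotype table."""
    cells = {gg: (int(np.sum(y[g == gg])), int(np.sum(g == gg))) for gg in (0, 1, 2)}
    a = b = 0.0
    for _ in range(200):
        grad = np.zeros(2)
        hess = np.zeros((2, 2))
        for gg, (n1, ntot) in cells.items():
            p = 1.0 / (1.0 + np.exp(-(a + b * gg)))
            grad += np.array([n1 - ntot * p, gg * (n1 - ntot * p)])
            w = ntot * p * (1 - p)
            hess += w * np.array([[1, gg], [gg, gg * gg]])
        step = np.linalg.solve(hess, grad)
        a, b = a + step[0], b + step[1]
        if np.abs(step).max() < tol:
            break
    return b


def test_no_covariate_fit_matches_newton_oracle():
    rng = np.random.default_rng(7)
    n = 2000
    g = rng.binomial(2, 0.3, n).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + 0.25 * g)))).astype(int)
    r = assoc.trend_test(g, _samples(y), covariates=[])
    assert r.beta == pytest.approx(_newton_2x3(g, y), abs=1e-8)


def test_independent_covariate_barely_moves_beta():
    """A covariate unrelated to outcome and dosage shifts beta only through
    non-collapsibility / nuisance-estimation noise: O(1e-4) at n=10,000."""
    rng = np.random.default_rng(42)
    n = 10_000
    g = rng.binomial(2, 0.3, n).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.3 * g)))).astype(int)
    samples = _samples(y)
    b0 = assoc.trend_test(g, samples, covariates=[]).beta
    b1 = assoc.trend_test(g, samples, covariates=["sex"]).beta
    assert abs(b1 - b0) < 1e-3
    assert abs(b1 - b0) < 0.01 * abs(b0)


def test_wald_close_to_lrt():
    rng = np.random.default_rng(3)
    n = 1500
    g = rng.binomial(2, 0.25, n).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 0.3 * g)))).astype(int)
    samples = _samples(y)
    wald = assoc.trend_test(g, samples, covariates=["age", "sex"])
    lrt = assoc.trend_test(g, samples, covariates=["age", "sex"], lrt=True)
    assert abs(np.log10(wald.p_trend) - np.log10(lrt.p_trend)) < 0.2


def test_constant_dosage_and_separation_are_flagged():
    y = np.array([1] * 30 + [0] * 30)
    const = assoc.trend_test(np.ones(60), _samples(y), covariates=[])
    assert not const.ok and "constant" in const.reason
    # perfect separation: dosage 2 only in cases
    g = np.array([2.0] * 30 + [0.0] * 30)
    sep = assoc.trend_test(g, _samples(y), covariates=[])
    assert not sep.ok


def test_score_scan_matches_wald_and_is_uniform_under_permuted_labels(small_dataset):
    ds = small_dataset
    kept, _ = assoc.maf_filter(ds.genotypes, ds.samples, 0.05)
    sub = ds.genotypes.subset_snps(kept[:30])
    p_score = assoc.score_scan(sub, ds.samples)
    p_wald = np.array(
        [assoc.trend_test(sub.column(s), ds.samples, snp_id=s).p_trend
         for s in sub.snps]
    )
    assert np.max(np.abs(np.log10(p_score) - np.log10(p_wald))) < 0.2

    # permuted case/control labels: p-values uniform
    rng = np.random.default_rng(11)
    shuffled = ds.samples.copy()
    shuffled["status"] = rng.permutation(shuffled["status"].to_numpy())
    p_null = assoc.score_scan(ds.genotypes, shuffled)
    assert stats.kstest(p_null, "uniform").pvalue > 0.01


# ------------------------------------------------------------- gene reduction


def _map(gene_to_snps):
    s2g = {}
    for g, snps in gene_to_snps.items():
        for s in snps:
            s2g.setdefault(s, []).append(g)
    return SnpGeneMap({s: sorted(g) for s, g in s2g.items()}, gene_to_snps)


def test_best_snp_per_gene_minimum_and_rank():
    m = _map({"gene": ["a", "b", "c"]})
    res = assoc.best_snp_per_gene(m, {"a": 0.4, "b": 0.01, "c": 0.2})
    (g,) = res
    assert g.best_snp_id == "b"
    assert g.p_j == 0.01
    assert g.r_j == pytest.approx(2.0)
    assert g.snp_rank == 1
    assert g.n_snps == 3


def test_best_snp_tie_breaks_lexicographically():
    m = _map({"gene": ["zz", "aa"]})
    (g,) = assoc.best_snp_per_gene(m, {"zz": 0.01, "aa": 0.01})
    assert g.best_snp_id == "aa"


def test_best_snp_invariant_to_input_order():
    p = {"a": 0.3, "b": 0.05, "c": 0.9}
    r1 = assoc.best_snp_per_gene(_map({"g": ["a", "b", "c"]}), p)
    r2 = assoc.best_snp_per_gene(_map({"g": ["c", "b", "a"]}), p)
    assert r1 == r2


def test_pooled_unit_p_never_exceeds_member_p():
    p = {"a": 0.3, "b": 0.05, "c": 0.9, "d": 0.4}
    separate = assoc.best_snp_per_gene(_map({"g1": ["a", "b"], "g2": ["c", "d"]}), p)
    pooled = assoc.best_snp_per_gene(_map({"g1|g2": ["a", "b", "c", "d"]}), p)
    assert pooled[0].p_j <= min(r.p_j for r in separate)


def test_gene_p_matrix_agrees_with_best_snp(small_dataset):
    ds = small_dataset
    from pathgwas import annotation as ann

    smap = ann.map_snps_to_genes(ds.annotation.snp_table, ds.annotation.genes)
    kept, _ = assoc.maf_filter(ds.genotypes, ds.samples, 0.01)
    mapped = [s for s in kept if s in smap.snp_to_genes]
    sub = ds.genotypes.subset_snps(mapped)
    p = assoc.score_scan(sub, ds.samples)
    genes, mat = assoc.gene_p_matrix(smap, mapped, p[None, :])
    by_gene = {g.gene_id: g.p_j for g in
               assoc.best_snp_per_gene(smap, dict(zip(mapped, p)))}
    np.testing.assert_allclose(mat[0], [by_gene[g] for g in genes])
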