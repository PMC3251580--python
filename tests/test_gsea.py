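import numpy as np
import pytest

from pathgwas import gsea


def brute_force_es(gene_ids, r, members, weight_p=1.0):
    """Independent O(N*N_H) recomputation: explicit running sum, one step
    per ranked gene (same ordering convention: r descending, id tie-break)."""
    import math

    order = sorted(range(len(gene_ids)), key=lambda i: (-r[i], gene_ids[i]))
    hits = [gene_ids[i] in members for i in order]
    n, n_hit = len(order), sum(hits)
    n_r = math.fsum(abs(r[i]) ** weight_p for i, h in zip(order, hits) if h)
    running, best = 0.0, -np.inf
    for i, h in zip(order, hits):
        if h:
            running += abs(r[i]) ** weight_p / n_r
        else:
            running -= 1.0 / (n - n_hit)
        best = max(best, running)
    return best


def test_single_hit_at_top():
    assert gsea.enrichment_score(["g1", "g2"], np.array([1.0, 0.0]), {"g1"}) == 1.0


def test_hand_computed_running_sum():
    # member ranked third of four with r=(4,3,2,1): sums -1/3, -2/3, 1/3, 0
    es = gsea.enrichment_score(["g1", "g2", "g3", "g4"],
                               np.array([4.0, 3.0, 2.0, 1.0]), {"g3"})
    assert es == pytest.approx(1 / 3)


def test_non_members_below_last_member_do_not_matter():
    ids = ["a", "b", "c", "d", "e"]
    r1 = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    r2 = np.array([5.0, 4.0, 3.0, 1.0, 2.0])  # tail non-members reordered
    assert gsea.enrichment_score(ids, r1, {"a", "b"}) == gsea.enrichment_score(
        ids, r2, {"a", "b"}
    )


def test_degenerate_sets_raise_or_use_limit():
    ids = ["a", "b", "c"]
    r = np.array([2.0, 1.0, 0.5])
    with pytest.raises(ValueError):
        gsea.enrichment_score(ids, r, set())
    with pytest.raises(ValueError):
        gsea.enrichment_score(ids, r, set(ids))
    # all member weights zero -> defined limit -N_H/(N-N_H)
    es = gsea.enrichment_score(ids, np.array([1.0, 0.0, 0.0]), {"b", "c"})
    assert es == pytest.approx(-2.0)


def test_weight_zero_invariant_to_monotone_transform():
    rng = np.random.default_rng(1)
    ids = [f"g{i}" for i in range(30)]
    r = rng.random(30)
    members = set(ids[::4])
    a = gsea.enrichment_score(ids, r, members, weight_p=0.0)
    b = gsea.enrichment_score(ids, np.exp(3 * r), members, weight_p=0.0)
    assert a == pytest.approx(b)
    # with weight 1 the transform does change ES
    c = gsea.enrichment_score(ids, r, members, weight_p=1.0)
    d = gsea.enrichment_score(ids, np.exp(3 * r), members, weight_p=1.0)
    assert c != pytest.approx(d)


def test_streaming_equals_brute_force_on_random_instances():
    """Vectorized ES equals the explicit running-sum recomputation exactly."""
    rng = np.random.default_rng(123)
    for _ in range(300):
        n = int(rng.integers(2, 51))
        n_hit = int(rng.integers(1, min(n - 1, 10) + 1))
        ids = [f"g{i:03d}" for i in range(n)]
        r = np.round(rng.random(n) * 4, 3)
        members = set(rng.choice(ids, n_hit, replace=False))
        es = gsea.enrichment_score(ids, r, members)
        assert es == brute_force_es(ids, r, members)


def test_pvalue_counting():
    assert gsea.gsea_pvalue(5.0, np.arange(100)) == 0.95
    assert gsea.gsea_pvalue(0.0025, np.full(10000, 1.0)) == 1.0
    # count of 25 exceedances in 10000
    perm = np.concatenate([np.full(25, 2.0), np.full(9975, 0.0)])
    assert gsea.gsea_pvalue(1.0, perm) == 0.0025
    # obs above all perms -> 0, displayed as "<1/B"
    res = gsea.GseaResult("s", 1.0, 10, 2, 1.0, 0.0, 100)
    assert res.p_display == "<0.01"


def test_b_equals_one_gives_degenerate_p():
    assert gsea.gsea_pvalue(0.5, np.array([0.9])) == 1.0
    assert gsea.gsea_pvalue(0.5, np.array([0.1])) == 0.0


def test_permutation_engine_deterministic(small_dataset):
    ds = small_dataset
    a = gsea.make_permutations(ds.genotypes.n_samples, 10, seed=4)
    b = gsea.make_permutations(ds.genotypes.n_samples, 10, seed=4)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        gsea.make_permutations(10, 0, seed=1)


def test_gsea_all_matches_scalar_path(small_dataset):
    """The matrix ES route used for permutations equals the scalar API."""
    from pathgwas import annotation as ann, association as assoc

    ds = small_dataset
    smap = ann.map_snps_to_genes(ds.annotation.snp_table, ds.annotation.genes)
    kept, _ = assoc.maf_filter(ds.genotypes, ds.samples, 0.01)
    mapped = [s for s in kept if s in smap.snp_to_genes]
    sub = ds.genotypes.subset_snps(mapped)
    obs = assoc.score_scan(sub, ds.samples)
    genes, og = assoc.gene_p_matrix(smap, mapped, obs[None, :])
    db = ann.PathwayDB(
        {sid: ann.Pathway(sid, src, gs) for sid, src, gs in ds.annotation.pathways}
    )
    results, _ = gsea.gsea_all(genes, og[0], np.vstack([og, og]), db)
    r = -np.log10(og[0])
    for res in results:
        members = set(db[res.set_id].genes) & set(genes)
        assert res.es == pytest.approx(
            gsea.enrichment_score(genes, r, members), rel=1e-12
        )
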