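import filecmp

import numpy as np
import pytest
from scipy import stats

from pathgwas import annotation as ann
from pathgwas import association as assoc
from pathgwas import io as pio
from pathgwas import simulate as sim


def test_config_validation():
    with pytest.raises(ValueError, match="maf_range"):
        sim.SimConfig(maf_range=(0.001, 0.5))
    with pytest.raises(ValueError, match="block_size"):
        sim.SimConfig(n_snps=10, block_size=20)
    with pytest.raises(ValueError, match="log-OR vector"):
        sim.SimConfig(
            causal_spec=[sim.CausalPathway("PW0001", 1, (0.1, 0.1))]
        )


def test_independent_snps_when_rho_zero():
    cfg = sim.SimConfig(
        n_cases=(625,), n_controls=(625,), n_snps=20, block_size=10,
        snps_per_gene=5, within_block_rho=0.0, n_pathways=2,
        pathway_sizes=(2, 4), maf_range=(0.1, 0.5), seed=1,
    )
    gm, _ = sim.simulate_genotypes(cfg)  # cohort of 5000
    corr = np.corrcoef(gm.dosages[:, :10], rowvar=False)
    off = corr[~np.eye(10, dtype=bool)]
    assert np.max(np.abs(off)) < 0.05


def test_ld_present_when_rho_high():
    cfg = sim.SimConfig(
        n_cases=(625,), n_controls=(625,), n_snps=10, block_size=10,
        snps_per_gene=5, within_block_rho=0.9, n_pathways=2,
        pathway_sizes=(2, 2), maf_range=(0.2, 0.5), seed=2,
    )
    gm, _ = sim.simulate_genotypes(cfg)
    corr = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
    assert corr > 0.4


def test_empirical_maf_matches_drawn_maf():
    cfg = sim.SimConfig(
        n_cases=(625,), n_controls=(625,), n_snps=50, block_size=10,
        snps_per_gene=5, maf_range=(0.05, 0.5), n_pathways=2,
        pathway_sizes=(5, 10), seed=3,
    )
    gm, annotation = sim.simulate_genotypes(cfg)
    emp = gm.dosages.mean(axis=0) / 2  # 5000 samples
    assert np.max(np.abs(emp - annotation.true_maf)) < 0.02


def test_dosages_in_support_and_counts(small_dataset):
    ds = small_dataset
    vals = ds.genotypes.dosages
    assert set(np.unique(vals[~np.isnan(vals)])) <= {0.0, 1.0, 2.0}
    counts = ds.samples.groupby("study")["status"].agg(["sum", "count"])
    assert (counts["sum"] == 40).all()
    assert (counts["count"] == 80).all()


def test_intended_snp_gene_map_recovered(small_dataset):
    ds = small_dataset
    smap = ann.map_snps_to_genes(ds.annotation.snp_table, ds.annotation.genes)
    assert smap.gene_to_snps == ds.annotation.gene_to_snps


def test_same_seed_byte_identical_files(tmp_path):
    cfg = dict(
        n_cases=(30,) * 2, n_controls=(30,) * 2, n_snps=50, block_size=10,
        snps_per_gene=5, n_pathways=5, pathway_sizes=(3, 8), seed=9,
    )
    for d in ("a", "b"):
        sim.write_dataset(sim.simulate_dataset(sim.SimConfig(**cfg)), tmp_path / d)
    for f in ["genotypes.tsv", "samples.tsv", "snps.tsv", "genes.bed",
              "pathways.gmt", "truth.json", "metadata.json"]:
        assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f


def test_roundtrip_through_readers(tmp_path):
    cfg = sim.SimConfig(
        n_cases=(30,), n_controls=(30,), n_snps=20, block_size=10,
        snps_per_gene=5, n_pathways=3, pathway_sizes=(2, 4),
        missing_rate=0.05, seed=4,
    )
    ds = sim.simulate_dataset(cfg)
    sim.write_dataset(ds, tmp_path)
    gm = pio.read_genotypes(tmp_path / "genotypes.tsv")
    assert gm.samples == ds.genotypes.samples
    np.testing.assert_array_equal(gm.dosages, ds.genotypes.dosages)
    samples = pio.read_samples(tmp_path / "samples.tsv")
    assert samples.equals(ds.samples.reset_index(drop=True))
    assert pio.read_gene_bed(tmp_path / "genes.bed") == ds.annotation.genes
    gmt = pio.read_gmt(tmp_path / "pathways.gmt")
    assert len(gmt) == cfg.n_pathways
    assert gmt == ds.annotation.pathways
    truth = pio.GroundTruth.from_json(tmp_path / "truth.json")
    assert truth.causal_snps == ds.truth.causal_snps


def test_quota_error_advises_multiplier():
    cfg = sim.SimConfig(
        n_cases=(500,), n_controls=(100,), n_snps=10, block_size=10,
        snps_per_gene=5, n_pathways=2, pathway_sizes=(2, 2),
        cohort_multiplier=1.05, seed=5,
    )
    with pytest.raises(ValueError, match="cohort_multiplier"):
        sim.simulate_dataset(cfg)


def test_global_null_trend_pvalues_uniform():
    cfg = sim.SimConfig(
        n_cases=(150,) * 2, n_controls=(150,) * 2, n_snps=2000, block_size=10,
        snps_per_gene=5, n_pathways=2, pathway_sizes=(5, 10),
        maf_range=(0.05, 0.5), seed=6,
    )
    ds = sim.simulate_dataset(cfg)
    p = assoc.score_scan(ds.genotypes, ds.samples)
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_causal_or_recovered_within_wald_band():
    """Single causal SNP at OR 1.5: estimate in [1.3, 1.7] in >=90% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(1, n_seeds + 1):
        cfg = sim.SimConfig(
            n_cases=(1000,), n_controls=(1000,), n_snps=10, block_size=10,
            snps_per_gene=5, n_pathways=2, pathway_sizes=(2, 2),
            maf_range=(0.2, 0.5),
            causal_spec=[sim.CausalPathway("PW0001", 1, (np.log(1.5),))],
            seed=seed,
        )
        ds = sim.simulate_dataset(cfg)
        snp = next(iter(ds.truth.causal_snps))
        r = assoc.trend_test(ds.genotypes.column(snp), ds.samples, covariates=[])
        hits += 1.3 <= r.or_ <= 1.7
    assert hits >= 0.9 * n_seeds


def test_write_dataset_rejects_id_mismatch(tmp_path, small_dataset):
    ds = small_dataset
    broken = sim.SimulatedDataset(
        ds.genotypes,
        ds.samples.assign(sample_id=lambda d: d["sample_id"].str.replace("S", "X")),
        ds.annotation,
        ds.truth,
        ds.config,
    )
    with pytest.raises(ValueError, match="X0"):
        sim.write_dataset(broken, tmp_path)
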