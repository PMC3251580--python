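import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathgwas import annotation as ann
from pathgwas import io as pio


@pytest.fixture
def gmt_db(tmp_path):
    entries = [
        ("pw_small", "KEGG", ["g1", "g2", "g3", "g4"]),
        ("pw_five", "Reactome", ["g1", "g2", "g3", "g4", "g5"]),
        ("pw_dup", "Self", ["g1", "g1", "g2", "g3", "g4", "g5"]),
        ("pw_big", "PID", [f"g{i}" for i in range(101)]),
    ]
    path = tmp_path / "sets.gmt"
    pio.write_gmt(entries, path)
    return ann.load_gene_sets(path)


def test_load_gene_sets_dedups_and_labels(gmt_db):
    assert len(gmt_db) == 4
    assert gmt_db["pw_dup"].size == 5  # duplicate counted once
    assert gmt_db["pw_five"].source == "Reactome"


def test_load_empty_gmt(tmp_path):
    path = tmp_path / "empty.gmt"
    path.write_text("")
    assert len(ann.load_gene_sets(path)) == 0


def test_filter_pathways_inclusive_bounds(gmt_db):
    kept = ann.filter_pathways(gmt_db, 5, 100)
    assert sorted(kept.ids()) == ["pw_dup", "pw_five"]  # sizes 4 and 101 dropped
    assert len(ann.filter_pathways(gmt_db, 1, 10**9)) == len(gmt_db)
    assert len(ann.filter_pathways(gmt_db, 200, 300)) == 0
    with pytest.raises(ValueError):
        ann.filter_pathways(gmt_db, 10, 5)


def test_overlap_conventions(gmt_db):
    assert ann.pathway_overlap(gmt_db, "pw_five", "pw_five") == 100.0
    # nested: pw_five (5 genes) inside pw_big
    assert ann.pathway_overlap(gmt_db, "pw_five", "pw_big") == 100.0
    assert ann.pathway_overlap(gmt_db, "pw_five", "pw_big", "union") == pytest.approx(
        100 * 5 / 101
    )
    with pytest.raises(KeyError):
        ann.pathway_overlap(gmt_db, "pw_five", "nope")


def test_overlap_half_shared():
    db = ann.PathwayDB(
        {
            "a": ann.Pathway("a", "Self", [f"g{i}" for i in range(10)]),
            "b": ann.Pathway("b", "Self", [f"g{i}" for i in range(5, 25)]),
        }
    )
    # |A|=10, |B|=20, 5 shared -> 100*5/min(10,20) = 50
    assert ann.pathway_overlap(db, "a", "b") == 50.0


@pytest.fixture
def snp_frame():
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(6)],
            "chrom": ["chr1"] * 5 + ["chrX"],
            "pos": [79_999, 80_000, 110_000, 130_000, 140_000, 500],
            "allele_a": "A",
            "allele_b": "G",
        }
    )


def test_map_boundaries_and_strand(snp_frame):
    plus = ann.GeneModel("gp", "chr1", 100_000, 120_000, "+")
    minus = ann.GeneModel("gm", "chr1", 100_000, 120_000, "-")
    m = ann.map_snps_to_genes(snp_frame, [plus])
    # + strand window [80000, 130000]: 79999 out, 80000 in, 130000 in, 140000 out
    assert sorted(m.gene_to_snps["gp"]) == ["s1", "s2", "s3"]
    m2 = ann.map_snps_to_genes(snp_frame, [minus])
    # - strand window [90000, 140000]: 20 kb on the 5' (right) side
    assert sorted(m2.gene_to_snps["gm"]) == ["s2", "s3", "s4"]


def test_map_snp_in_two_overlapping_genes(snp_frame):
    g1 = ann.GeneModel("g1", "chr1", 100_000, 120_000, "+")
    g2 = ann.GeneModel("g2", "chr1", 105_000, 125_000, "+")
    m = ann.map_snps_to_genes(snp_frame, [g1, g2])
    assert m.snp_to_genes["s2"] == ["g1", "g2"]


def test_map_idempotent_and_order_independent(snp_frame):
    genes = [
        ann.GeneModel("g1", "chr1", 100_000, 120_000, "+"),
        ann.GeneModel("g2", "chr1", 105_000, 125_000, "-"),
    ]
    a = ann.map_snps_to_genes(snp_frame, genes)
    b = ann.map_snps_to_genes(snp_frame.iloc[::-1], list(reversed(genes)))
    assert a.snp_to_genes == b.snp_to_genes
    assert {g: sorted(s) for g, s in a.gene_to_snps.items()} == {
        g: sorted(s) for g, s in b.gene_to_snps.items()
    }


def _chain_map(pairs, singletons=()):
    gene_to_snps = {}
    snp_to_genes = {}
    for i, (a, b) in enumerate(pairs):
        s = f"shared{i}"
        gene_to_snps.setdefault(a, []).append(s)
        gene_to_snps.setdefault(b, []).append(s)
        snp_to_genes[s] = sorted([a, b])
    for g in singletons:
        s = f"solo_{g}"
        gene_to_snps[g] = [s]
        snp_to_genes[s] = [g]
    return ann.SnpGeneMap(snp_to_genes, gene_to_snps)


def test_pooling_transitive_chain():
    m = _chain_map([("A", "B"), ("B", "C")], singletons=["D"])
    units = ann.pool_shared_loci(m)
    sizes = sorted(len(u.genes) for u in units)
    assert sizes == [1, 3]
    big = next(u for u in units if len(u.genes) == 3)
    assert big.genes == ["A", "B", "C"]
    assert set(big.snps) == {"shared0", "shared1"}


def test_pooling_no_shared_snps_gives_singletons():
    m = _chain_map([], singletons=["A", "B", "C"])
    units = ann.pool_shared_loci(m)
    assert [u.genes for u in units] == [["A"], ["B"], ["C"]]


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 15), st.integers(0, 15)), max_size=20))
def test_pooling_partitions_genes(pairs):
    """Units always partition the pooled genes and never outnumber them."""
    named = [(f"G{a}", f"G{b}") for a, b in pairs]
    genes = sorted({g for p in named for g in p})
    m = _chain_map(named)
    units = ann.pool_shared_loci(m)
    members = [g for u in units for g in u.genes]
    assert sorted(members) == genes          # partition, no duplicates
    assert len(units) <= max(len(genes), 1)  # pooling never increases count


def test_drop_snps_removes_empty_genes():
    m = _chain_map([("A", "B")], singletons=["C"])
    filtered = m.drop_snps({"solo_C"})
    assert "C" not in filtered.gene_to_snps
    assert set(filtered.gene_to_snps) == {"A", "B"}
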