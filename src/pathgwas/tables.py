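"""Packaged per-gene association tables from a published multi-study
bladder-cancer GWAS pathway analysis.

Four gene tables (aromatic amine metabolism; NAD metabolism; clathrin-
mediated vesicle pathways; mitotic metaphase/anaphase transition) are
shipped as TSV fixtures with columns ``gene, n_snps, best_snp, snp_rank,
maf, or, ci_low, ci_high, p`` (the NAD and clathrin tables carry an extra
``pathway`` membership label).  They serve as worked examples: counting
rows under a predicate (a p-value cut, a gene-name exclusion, a membership
label) reproduces the narrative counts of the source analysis, and the
aromatic-amine locus structure drives the locus-pooling worked example.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TABLE_NAMES = (
    "aromatic_amine",
    "nad_metabolism",
    "clathrin_vesicle",
    "mitotic_transition",
)

_FILES = {
    "aromatic_amine": "aromatic_amine_genes.tsv",
    "nad_metabolism": "nad_metabolism_genes.tsv",
    "clathrin_vesicle": "clathrin_vesicle_genes.tsv",
    "mitotic_transition": "mitotic_transition_genes.tsv",
}

EXPECTED_ROWS = {
    "aromatic_amine": 11,
    "nad_metabolism": 11,
    "clathrin_vesicle": 21,
    "mitotic_transition": 8,
}

# genes in the aromatic-amine pathway that sit on shared chromosomal loci and
# are tagged by overlapping SNPs; pooling them into single units reduces the
# 11 genes to 7 analysis units
AA_SHARED_LOCI = (
    ("CYP1A1", "CYP1A2"),
    ("UGT1A4", "UGT1A6", "UGT1A9"),
    ("SULT1A1", "SULT1A2"),
)


def aa_locus_map():
    """SNP-gene map encoding the aromatic-amine pathway's locus structure.

    Genes inside each shared locus are linked by a common tagging SNP (a
    chain suffices: pooling is transitively closed); every other gene gets
    a private SNP.  Pooling this map reduces the 11 genes to 7 units.
    """
    from pathgwas.annotation import SnpGeneMap

    genes = load_gene_table("aromatic_amine")["gene"].tolist()
    gene_to_snps: dict[str, list[str]] = {g: [f"snp_{g}"] for g in genes}
    for li, locus in enumerate(AA_SHARED_LOCI):
        for a, b in zip(locus, locus[1:]):
            shared = f"snp_shared_{li}_{a}_{b}"
            gene_to_snps[a].append(shared)
            gene_to_snps[b].append(shared)
    snp_to_genes: dict[str, list[str]] = {}
    for g, snps in gene_to_snps.items():
        for s in snps:
            snp_to_genes.setdefault(s, []).append(g)
    snp_to_genes = {s: sorted(gs) for s, gs in snp_to_genes.items()}
    return SnpGeneMap(snp_to_genes, gene_to_snps)


def load_gene_table(name: str) -> pd.DataFrame:
    if name not in _FILES:
        raise KeyError(f"unknown table {name!r}; choose from {TABLE_NAMES}")
    ref = resources.files("pathgwas") / "data" / _FILES[name]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if len(df) != EXPECTED_ROWS[name]:
        raise ValueError(
            f"{name}: expected {EXPECTED_ROWS[name]} rows, found {len(df)}"
        )
    return df


def table_filter_count(df: pd.DataFrame, predicate) -> int:
    """Rows satisfying a predicate.

    ``predicate`` is either a pandas ``query`` string (unknown columns raise)
    or a callable mapping the frame to a boolean Series.
    """
    if callable(predicate):
        mask = predicate(df)
        return int(mask.sum())
    try:
        return int(len(df.query(predicate)))
    except Exception as exc:
        raise ValueError(f"bad predicate {predicate!r}: {exc}") from exc
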