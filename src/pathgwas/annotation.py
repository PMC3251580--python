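"""Pathway database and SNP-to-gene mapping.

Genes are assigned the SNPs falling in a window extending 20 kb beyond the
5' end and 10 kb beyond the 3' end of the coding region (strand-aware), the
window commonly used to capture cis-regulatory variation while limiting
overlap between neighbouring genes.  Gene sets are filtered to 5-100 members
so that neither trivially narrow nor catch-all categories are tested.  Genes
that share mapped SNPs (e.g. tandem paralogue clusters tagged by the same
variants) can be pooled into single locus units so one association signal is
not counted several times within a pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pathgwas import io as pio

logger = logging.getLogger(__name__)

PATHWAY_SOURCES = ("BioCarta", "KEGG", "PID", "Reactome", "HumanCyc", "Self")


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding-region span, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    def region(self, upstream: int = 20_000, downstream: int = 10_000) -> tuple[int, int]:
        """Mapped region: upstream of the 5' end, downstream of the 3' end.

        For a + strand gene the 5' end is ``start``; for a - strand gene it
        is ``end``.  Bounds are inclusive and clipped at 1.
        """
        if self.strand == "+":
            lo, hi = self.start - upstream, self.end + downstream
        else:
            lo, hi = self.start - downstream, self.end + upstream
        return max(1, lo), hi


@dataclass
class Pathway:
    set_id: str
    source: str
    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class PathwayDB:
    """Collection of gene sets keyed by set id."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, set_id: str) -> Pathway:
        try:
            return self.pathways[set_id]
        except KeyError:
            raise KeyError(f"unknown pathway id {set_id!r}") from None

    def __iter__(self):
        return iter(self.pathways.values())

    def ids(self) -> list[str]:
        return list(self.pathways)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for pw in self:
            out.update(pw.genes)
        return out


def load_gene_sets(gmt_path) -> PathwayDB:
    """Load a GMT file; duplicate genes within a set are dropped with a warning."""
    db = PathwayDB()
    entries = pio.read_gmt(gmt_path)
    if not entries:
        logger.warning("%s: empty GMT file, empty pathway database", gmt_path)
    for set_id, source, genes in entries:
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.warning(
                "%s: %d duplicate gene(s) dropped in set %s",
                gmt_path, len(genes) - len(deduped), set_id,
            )
        db.pathways[set_id] = Pathway(set_id, source, deduped)
    return db


def filter_pathways(db: PathwayDB, min_genes: int = 5, max_genes: int = 100) -> PathwayDB:
    """Keep sets with ``min_genes <= size <= max_genes`` (bounds inclusive)."""
    if min_genes > max_genes:
        raise ValueError(f"min_genes {min_genes} > max_genes {max_genes}")
    kept = {
        sid: pw for sid, pw in db.pathways.items() if min_genes <= pw.size <= max_genes
    }
    if not kept and db.pathways:
        logger.warning("size filter [%d, %d] removed every pathway", min_genes, max_genes)
    return PathwayDB(kept)


def restrict_to_genes(db: PathwayDB, known_genes: set[str]) -> PathwayDB:
    """Drop set members without coordinates / data, logging the count."""
    out = PathwayDB()
    dropped = 0
    for pw in db:
        genes = [g for g in pw.genes if g in known_genes]
        dropped += pw.size - len(genes)
        if genes:
            out.pathways[pw.set_id] = Pathway(pw.set_id, pw.source, genes)
    if dropped:
        logger.info("dropped %d set member(s) absent from the gene table", dropped)
    return out


def pathway_overlap(db: PathwayDB, id_a: str, id_b: str, denominator: str = "min") -> float:
    """Percentage of genes shared between two pathways.

    ``100 * |A ∩ B| / d`` where ``d`` is ``min(N_A, N_B)`` (default; keeps
    nested sets at 100%), ``|A ∪ B|``, or ``mean(N_A, N_B)``.
    """
    a = set(db[id_a].genes)
    b = set(db[id_b].genes)
    inter = len(a & b)
    if denominator == "min":
        d = min(len(a), len(b))
    elif denominator == "union":
        d = len(a | b)
    elif denominator == "mean":
        d = (len(a) + len(b)) / 2
    else:
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    return 100.0 * inter / d if d else 0.0


@dataclass
class LocusUnit:
    """A pooled analysis unit: genes joined because they share mapped SNPs."""

    unit_id: str
    genes: list[str]
    snps: list[str]


@dataclass
class SnpGeneMap:
    """Bidirectional SNP <-> gene assignment plus optional pooled locus units."""

    snp_to_genes: dict[str, list[str]]
    gene_to_snps: dict[str, list[str]]
    units: list[LocusUnit] | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_snps)

    @property
    def snps(self) -> list[str]:
        return list(self.snp_to_genes)

    def drop_snps(self, removed: set[str]) -> "SnpGeneMap":
        """New map without ``removed``; genes left with no SNPs are dropped."""
        g2s = {}
        for g, snps in self.gene_to_snps.items():
            kept = [s for s in snps if s not in removed]
            if kept:
                g2s[g] = kept
        s2g: dict[str, list[str]] = {}
        for g, snps in g2s.items():
            for s in snps:
                s2g.setdefault(s, []).append(g)
        # keep SNP order stable and gene lists sorted for determinism
        s2g = {s: sorted(gs) for s, gs in s2g.items()}
        return SnpGeneMap(s2g, g2s)


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: list[GeneModel],
    upstream: int = 20_000,
    downstream: int = 10_000,
) -> SnpGeneMap:
    """Assign each SNP to every gene whose extended region contains it.

    ``snps`` is the SNP table (``snp_id, chrom, pos`` used).  A SNP falling
    in two overlapping gene regions appears under both genes.  SNPs on
    chromosomes absent from the gene table are skipped with a warning.
    """
    gene_ids_seen = set()
    for g in genes:
        if g.gene_id in gene_ids_seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r} in gene table")
        gene_ids_seen.add(g.gene_id)

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        lo, hi = g.region(upstream, downstream)
        by_chrom.setdefault(g.chrom, []).append((lo, hi, g.gene_id))

    snp_to_genes: dict[str, list[str]] = {}
    gene_to_snps: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    unknown_chroms = set(snps["chrom"].unique()) - set(by_chrom)
    if unknown_chroms:
        logger.warning(
            "skipping SNPs on chromosome(s) with no genes: %s", sorted(unknown_chroms)
        )
    for chrom, grp in snps.groupby("chrom", sort=False):
        regions = by_chrom.get(chrom)
        if regions is None:
            continue
        lo = np.array([r[0] for r in regions])
        hi = np.array([r[1] for r in regions])
        names = [r[2] for r in regions]
        pos = grp["pos"].to_numpy()
        ids = grp["snp_id"].tolist()
        inside = (pos[:, None] >= lo[None, :]) & (pos[:, None] <= hi[None, :])
        for i, snp_id in enumerate(ids):
            hits = [names[j] for j in np.flatnonzero(inside[i])]
            if hits:
                snp_to_genes[snp_id] = sorted(hits)
                for gname in hits:
                    gene_to_snps[gname].append(snp_id)
    gene_to_snps = {g: snps_ for g, snps_ in gene_to_snps.items() if snps_}
    return SnpGeneMap(snp_to_genes, gene_to_snps)


def pool_shared_loci(smap: SnpGeneMap, genes: list[str] | None = None) -> list[LocusUnit]:
    """Union-find over genes: two genes join one unit iff they share >=1 SNP.

    The relation is transitively closed; each unit's SNP set is the union of
    its members' SNPs.  ``genes`` restricts pooling to a subset (e.g. one
    pathway's genes); by default every mapped gene participates.
    """
    pool = sorted(smap.gene_to_snps) if genes is None else sorted(genes)
    pool = [g for g in pool if g in smap.gene_to_snps]
    parent = {g: g for g in pool}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    in_pool = set(pool)
    for snp, snp_genes in smap.snp_to_genes.items():
        members = [g for g in snp_genes if g in in_pool]
        for other in members[1:]:
            union(members[0], other)

    groups: dict[str, list[str]] = {}
    for g in pool:
        groups.setdefault(find(g), []).append(g)

    units = []
    for root in sorted(groups):
        members = sorted(groups[root])
        snps = sorted({s for g in members for s in smap.gene_to_snps[g]})
        units.append(LocusUnit(unit_id="|".join(members), genes=members, snps=snps))
    return units


def unit_map(smap: SnpGeneMap, units: list[LocusUnit]) -> SnpGeneMap:
    """A SnpGeneMap whose 'genes' are pooled locus units."""
    g2s = {u.unit_id: list(u.snps) for u in units}
    s2g: dict[str, list[str]] = {}
    for uid, snps in g2s.items():
        for s in snps:
            s2g.setdefault(s, []).append(uid)
    s2g = {s: sorted(gs) for s, gs in s2g.items()}
    return SnpGeneMap(s2g, g2s, units=units)


def units_report(units: list[LocusUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "member_genes": [",".join(u.genes) for u in units],
            "n_snps": [len(u.snps) for u in units],
        }
    )


def pathway_genes_as_units(pw: Pathway, units: list[LocusUnit]) -> list[str]:
    """Translate a pathway's gene list into locus-unit ids (deduplicated)."""
    gene_to_unit = {}
    for u in units:
        for g in u.genes:
            gene_to_unit[g] = u.unit_id
    out = []
    for g in pw.genes:
        uid = gene_to_unit.get(g)
        if uid is not None and uid not in out:
            out.append(uid)
    return out
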