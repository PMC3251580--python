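"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* genotype TSV — header ``sample_id`` followed by SNP ids; cells are additive
  minor-allele dosages ``0/1/2`` or ``NA`` for missing.
* sample TSV — ``sample_id, status, age, sex, study, dna_source, smoking``
  with ``status`` 0/1 (1 = case), ``sex`` and ``dna_source`` 0/1, ``smoking``
  one of ``never/former/occasional/current``.
* SNP table TSV — ``snp_id, chrom, pos, allele_a, allele_b`` (1-based
  positions).
* gene BED — BED6 (0-based half-open, strand in column 6); converted to
  1-based inclusive coordinates on read.
* pathway GMT — ``set_id<TAB>source<TAB>gene1<TAB>...``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SMOKING_LEVELS = ("never", "former", "occasional", "current")

SAMPLE_COLUMNS = ["sample_id", "status", "age", "sex", "study", "dna_source", "smoking"]
SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix.

    ``dosages`` is float64 with ``np.nan`` marking missing calls; the
    permutation unit in the pathway analysis is a whole row (one sample's
    genotype vector), which preserves LD between SNPs.
    """

    samples: list[str]
    snps: list[str]
    dosages: np.ndarray  # shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages must be 0/1/2/NA; found {bad[:5]}")
        self._snp_index = {s: i for i, s in enumerate(self.snps)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._snp_index[snp_id]]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self._snp_index[s] for s in snp_ids]
        return GenotypeMatrix(self.samples, list(snp_ids), self.dosages[:, idx])


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    samples = df["sample_id"].tolist()
    snps = df.columns[1:].tolist()
    return GenotypeMatrix(samples, snps, df.iloc[:, 1:].to_numpy(dtype=float))


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.snps)
    # integer rendering with NA for missing
    df = df.astype("Int64")
    df.insert(0, "sample_id", gm.samples)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample columns {sorted(missing)}")
    bad = set(df["smoking"].unique()) - set(SMOKING_LEVELS)
    if bad:
        raise ValueError(f"{path}: unknown smoking levels {sorted(bad)}")
    if df[SAMPLE_COLUMNS].isna().any().any():
        raise ValueError(f"{path}: covariate missingness is not supported")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SNP columns {sorted(missing)}")
    return df


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    snps[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_bed(path: str | Path):
    """Read a BED6 gene table into :class:`~pathgwas.annotation.GeneModel`s.

    BED intervals are 0-based half-open; internal coordinates are 1-based
    inclusive, so ``start = bed_start + 1`` and ``end = bed_end``.
    """
    from pathgwas.annotation import GeneModel

    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 line needs 6 fields, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    strand=strand,
                )
            )
    return genes


def write_gene_bed(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into ``(set_id, source, genes)`` tuples.

    Raises ``ValueError`` with the line number on lines with fewer than three
    fields (set id, source/description, at least one gene).
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 tab-separated fields")
            out.append((parts[0], parts[1], parts[2:]))
    return out


def write_gmt(entries, path: str | Path) -> None:
    """Write ``(set_id, source, genes)`` tuples as GMT."""
    with open(path, "w") as fh:
        for set_id, source, genes in entries:
            fh.write("\t".join([set_id, source, *genes]) + "\n")


@dataclass
class GroundTruth:
    """Known effect configuration of a simulated dataset.

    ``causal_snps`` maps snp_id -> per-study log-OR vector; a SNP is
    heterogeneous when that vector is non-constant.
    """

    causal_snps: dict[str, list[float]] = field(default_factory=dict)
    enriched_pathways: list[str] = field(default_factory=list)
    heterogeneous_snps: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "causal_snps": self.causal_snps,
                    "enriched_pathways": self.enriched_pathways,
                    "heterogeneous_snps": self.heterogeneous_snps,
                    "meta": self.meta,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            causal_snps=d["causal_snps"],
            enriched_pathways=d["enriched_pathways"],
            heterogeneous_snps=d["heterogeneous_snps"],
            meta=d.get("meta", {}),
        )
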