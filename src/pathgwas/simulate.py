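"""Synthetic multi-study case-control GWAS data with known effect structure.

The generator emulates the structure the pathway analysis assumes: several
case-control studies genotyped on a common SNP panel, LD between nearby
SNPs, genes laid out so the 20 kb/10 kb window rule recovers an intended
SNP-to-gene map, pathways of 5-100 genes, and a disease model with
study-specific intercepts, covariate effects, and per-study per-allele
log-ORs at chosen causal SNPs (a non-constant per-study vector makes a SNP
heterogeneous, the target of the I2 filter).

Genotypes come from a latent-Gaussian copula: per LD block one AR(1)
Gaussian vector per haplotype, thresholded at each SNP's drawn MAF, two
haplotypes summed to a 0/1/2 dosage.  Case-control sampling is
retrospective: a cohort ``cohort_multiplier`` times the requested size is
simulated per study and the configured numbers of cases and controls are
subsampled, keeping the logistic trend test well-specified.

All randomness flows from a single seeded generator; the seed is recorded
in the output metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pathgwas import io as pio
from pathgwas.annotation import GeneModel
from pathgwas.io import SMOKING_LEVELS, GenotypeMatrix, GroundTruth

# paper-scale defaults: 3,532 cases and 5,120 controls over five studies
DEFAULT_CASES = (707, 706, 706, 707, 706)
DEFAULT_CONTROLS = (1024, 1024, 1024, 1024, 1024)

# per-allele ORs in published bladder-cancer gene tables span ~0.77-1.27,
# i.e. |log OR| up to ~0.26; causal_spec entries are chosen on that scale.


@dataclass
class CausalPathway:
    """One enriched pathway: n_causal member genes each get a causal SNP
    with the given per-study per-allele log-ORs."""

    pathway_id: str
    n_causal: int
    log_or_per_study: tuple[float, ...]


@dataclass
class SimConfig:
    n_cases: tuple[int, ...] = DEFAULT_CASES
    n_controls: tuple[int, ...] = DEFAULT_CONTROLS
    n_snps: int = 2000
    block_size: int = 10
    within_block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.01, 0.5)
    snps_per_gene: int = 5
    pathway_sizes: tuple[int, int] = (5, 100)
    n_pathways: int = 100
    causal_spec: list[CausalPathway] = field(default_factory=list)
    covariate_spec: dict = field(default_factory=dict)
    cohort_multiplier: float = 4.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.005 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie within [0.005, 0.5]")
        if len(self.n_cases) != len(self.n_controls):
            raise ValueError("n_cases and n_controls must have one entry per study")
        if min(self.n_cases) <= 0 or min(self.n_controls) <= 0:
            raise ValueError("per-study case/control counts must be positive")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if self.block_size > self.n_snps:
            raise ValueError(
                f"block_size {self.block_size} exceeds n_snps {self.n_snps}"
            )
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must lie in [0, 1)")
        if self.n_snps % self.block_size:
            raise ValueError("n_snps must be a multiple of block_size")
        if self.block_size % self.snps_per_gene:
            raise ValueError("block_size must be a multiple of snps_per_gene")
        if self.pathway_sizes[0] > self.pathway_sizes[1]:
            raise ValueError("pathway_sizes interval is inverted")
        for cs in self.causal_spec:
            if len(cs.log_or_per_study) != self.n_studies:
                raise ValueError(
                    f"{cs.pathway_id}: log-OR vector length "
                    f"{len(cs.log_or_per_study)} != {self.n_studies} studies"
                )

    @property
    def n_studies(self) -> int:
        return len(self.n_cases)

    @property
    def study_ids(self) -> list[str]:
        return [f"study{k + 1}" for k in range(self.n_studies)]

    @property
    def cohort_per_study(self) -> list[int]:
        return [
            int(np.ceil(self.cohort_multiplier * (c + u)))
            for c, u in zip(self.n_cases, self.n_controls)
        ]


# covariate distributions (synthetic; configurable via covariate_spec)
DEFAULT_COVARIATES = {
    "age_range": (40, 75),
    "sex_p": 0.5,
    "dna_source_p": 0.5,
    "smoking_p": (0.35, 0.30, 0.05, 0.30),  # never/former/occasional/current
}

# disease-model coefficients (logit scale)
DEFAULT_MODEL = {
    "intercept": -1.0,
    "study_offsets": (0.0, 0.1, -0.1, 0.05, -0.05),
    "age": 0.015,        # per year, centered at 55
    "sex": 0.25,
    "dna_source": 0.0,
    "smoking": (0.0, 0.3, 0.2, 0.7),  # never/former/occasional/current
}


@dataclass
class SnpAnnotation:
    """Synthetic annotation bundle: SNP coordinates, gene models, gene sets."""

    snp_table: pd.DataFrame
    genes: list[GeneModel]
    pathways: list[tuple[str, str, list[str]]]  # (set_id, source, genes)
    gene_to_snps: dict[str, list[str]]
    true_maf: np.ndarray | None = None  # drawn MAF per SNP (simulation truth)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SnpAnnotation]:
    """Cohort genotypes plus a consistent synthetic annotation.

    Blocks are placed 2 Mb apart on one synthetic chromosome; within a
    block, genes occupy disjoint 50 kb-separated spans whose SNPs sit inside
    the coding region, so the 20 kb/10 kb rule maps exactly the intended
    SNPs to each gene and no two genes share a SNP.
    """
    rng = np.random.default_rng(config.seed)
    n = int(np.sum(config.cohort_per_study))
    m = config.n_snps
    bs = config.block_size
    n_blocks = m // bs
    rho = config.within_block_rho

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresh = stats.norm.ppf(mafs)

    dosages = np.empty((n, m))
    scale = np.sqrt(1.0 - rho**2)
    for blk in range(n_blocks):
        sl = slice(blk * bs, (blk + 1) * bs)
        dose = np.zeros((n, bs))
        for _hap in range(2):
            eps = rng.standard_normal((n, bs))
            z = np.empty((n, bs))
            z[:, 0] = eps[:, 0]
            for j in range(1, bs):
                z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
            dose += (z < thresh[None, sl]).astype(float)
        dosages[:, sl] = dose
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    snp_ids = [f"snp{i + 1:06d}" for i in range(m)]
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]

    # coordinates and gene layout
    genes_per_block = bs // config.snps_per_gene
    spacing = 1_000
    gene_gap = 50_000
    chrom = "chr1"
    pos = np.empty(m, dtype=int)
    genes: list[GeneModel] = []
    gene_to_snps: dict[str, list[str]] = {}
    gidx = 0
    for blk in range(n_blocks):
        base = 1_000_000 + blk * 2_000_000
        for gb in range(genes_per_block):
            gene_id = f"G{gidx + 1:05d}"
            gstart = base + gb * gene_gap
            first = blk * bs + gb * config.snps_per_gene
            snps_here = []
            for k in range(config.snps_per_gene):
                pos[first + k] = gstart + k * spacing
                snps_here.append(snp_ids[first + k])
            gend = gstart + (config.snps_per_gene - 1) * spacing
            strand = "+" if gidx % 2 == 0 else "-"
            genes.append(GeneModel(gene_id, chrom, gstart, gend, strand))
            gene_to_snps[gene_id] = snps_here
            gidx += 1

    snp_table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "allele_a": "A",
            "allele_b": "G",
        }
    )

    pathways = _make_pathways(config, [g.gene_id for g in genes], rng)
    gm = GenotypeMatrix(sample_ids, snp_ids, dosages)
    return gm, SnpAnnotation(snp_table, genes, pathways, gene_to_snps, true_maf=mafs)


def _make_pathways(
    config: SimConfig, gene_ids: list[str], rng: np.random.Generator
) -> list[tuple[str, str, list[str]]]:
    lo, hi = config.pathway_sizes
    hi = min(hi, len(gene_ids))
    lo = min(lo, hi)
    out = []
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(gene_ids, size=size, replace=False).tolist())
        out.append((f"PW{i + 1:04d}", "Self", members))
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    annotation: SnpAnnotation,
    config: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Disease status from a logistic model; retrospective case-control draw.

    Returns the retained sample table (ids reference genotype rows) and the
    ground truth.  Raises when the simulated cohort holds too few cases or
    controls to meet a study quota (increase ``cohort_multiplier``).
    """
    # derive the phenotype stream from the same master seed, offset so it is
    # independent of the genotype stream yet reproducible
    rng = np.random.default_rng((config.seed, 1))
    cov = {**DEFAULT_COVARIATES, **config.covariate_spec}
    model = {**DEFAULT_MODEL, **config.covariate_spec.get("model", {})}

    n = genotypes.n_samples
    cohort_sizes = config.cohort_per_study
    if sum(cohort_sizes) != n:
        raise ValueError(
            f"genotype cohort has {n} samples but config implies {sum(cohort_sizes)}"
        )
    study = np.repeat(config.study_ids, cohort_sizes)

    age = rng.integers(cov["age_range"][0], cov["age_range"][1] + 1, size=n)
    sex = (rng.random(n) < cov["sex_p"]).astype(int)
    dna = (rng.random(n) < cov["dna_source_p"]).astype(int)
    smoking_idx = rng.choice(len(SMOKING_LEVELS), size=n, p=cov["smoking_p"])
    smoking = np.array(SMOKING_LEVELS)[smoking_idx]

    offsets = model["study_offsets"]
    if len(offsets) < config.n_studies:
        offsets = tuple(offsets) + (0.0,) * (config.n_studies - len(offsets))
    study_offset = dict(zip(config.study_ids, offsets))
    logit = (
        model["intercept"]
        + np.array([study_offset[s] for s in study])
        + model["age"] * (age - 55)
        + model["sex"] * sex
        + model["dna_source"] * dna
        + np.array(model["smoking"])[smoking_idx]
    )

    truth = _resolve_causal(annotation, config)
    study_index = {s: k for k, s in enumerate(config.study_ids)}
    ks = np.array([study_index[s] for s in study])
    for snp_id, betas in truth.causal_snps.items():
        g = genotypes.column(snp_id)
        g = np.where(np.isnan(g), np.nanmean(g), g)
        logit = logit + np.array(betas)[ks] * g

    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    keep_idx: list[int] = []
    start = 0
    for k, size in enumerate(cohort_sizes):
        idx = np.arange(start, start + size)
        start += size
        cases = idx[y[idx] == 1]
        ctrls = idx[y[idx] == 0]
        need_ca, need_co = config.n_cases[k], config.n_controls[k]
        if cases.size < need_ca or ctrls.size < need_co:
            raise ValueError(
                f"{config.study_ids[k]}: cohort yielded {cases.size} cases / "
                f"{ctrls.size} controls; need {need_ca}/{need_co} — "
                "increase cohort_multiplier"
            )
        keep_idx.extend(rng.choice(cases, need_ca, replace=False).tolist())
        keep_idx.extend(rng.choice(ctrls, need_co, replace=False).tolist())
    keep = np.sort(np.array(keep_idx))

    samples = pd.DataFrame(
        {
            "sample_id": [genotypes.samples[i] for i in keep],
            "status": y[keep],
            "age": age[keep],
            "sex": sex[keep],
            "study": study[keep],
            "dna_source": dna[keep],
            "smoking": smoking[keep],
        }
    )
    truth.meta["seed"] = config.seed
    return samples, truth


def _resolve_causal(annotation: SnpAnnotation, config: SimConfig) -> GroundTruth:
    pw = {p[0]: p[2] for p in annotation.pathways}
    causal: dict[str, list[float]] = {}
    enriched = []
    for cs in config.causal_spec:
        if cs.pathway_id not in pw:
            raise ValueError(f"causal_spec names unknown pathway {cs.pathway_id!r}")
        members = [g for g in pw[cs.pathway_id] if g in annotation.gene_to_snps]
        if cs.n_causal > len(members):
            raise ValueError(
                f"{cs.pathway_id}: {cs.n_causal} causal genes requested, "
                f"{len(members)} mapped members available"
            )
        if any(b != 0 for b in cs.log_or_per_study):
            enriched.append(cs.pathway_id)
        for g in members[: cs.n_causal]:
            causal[annotation.gene_to_snps[g][0]] = list(cs.log_or_per_study)
    hetero = [
        s for s, betas in causal.items() if len(set(betas)) > 1
    ]
    return GroundTruth(
        causal_snps=causal, enriched_pathways=enriched, heterogeneous_snps=hetero
    )


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix  # retained case-control samples only
    samples: pd.DataFrame
    annotation: SnpAnnotation
    truth: GroundTruth
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Genotypes + phenotypes + annotation, restricted to retained samples."""
    cohort, annotation = simulate_genotypes(config)
    samples, truth = simulate_phenotypes(cohort, annotation, config)
    keep = samples["sample_id"].tolist()
    pos = {s: i for i, s in enumerate(cohort.samples)}
    idx = [pos[s] for s in keep]
    gm = GenotypeMatrix(keep, cohort.snps, cohort.dosages[idx])
    return SimulatedDataset(gm, samples, annotation, truth, config)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the full dataset in the pipeline's input formats.

    Validates id consistency across tables first; mismatches raise with the
    offending ids listed.
    """
    bad = sorted(set(ds.samples["sample_id"]) - set(ds.genotypes.samples))
    if bad:
        raise ValueError(f"sample ids missing from genotypes: {bad[:10]}")
    bad = sorted(set(ds.annotation.snp_table["snp_id"]) - set(ds.genotypes.snps))
    if bad:
        raise ValueError(f"snp ids missing from genotypes: {bad[:10]}")
    gene_ids = {g.gene_id for g in ds.annotation.genes}
    bad = sorted({g for _, _, gs in ds.annotation.pathways for g in gs} - gene_ids)
    if bad:
        raise ValueError(f"pathway genes missing from gene table: {bad[:10]}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_genotypes(ds.genotypes, outdir / "genotypes.tsv")
    pio.write_samples(ds.samples, outdir / "samples.tsv")
    pio.write_snp_table(ds.annotation.snp_table, outdir / "snps.tsv")
    pio.write_gene_bed(ds.annotation.genes, outdir / "genes.bed")
    pio.write_gmt(ds.annotation.pathways, outdir / "pathways.gmt")
    ds.truth.to_json(outdir / "truth.json")
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(
            {
                "seed": ds.config.seed,
                "n_cases": list(ds.config.n_cases),
                "n_controls": list(ds.config.n_controls),
                "n_snps": ds.config.n_snps,
                "block_size": ds.config.block_size,
                "within_block_rho": ds.config.within_block_rho,
                "maf_range": list(ds.config.maf_range),
                "snps_per_gene": ds.config.snps_per_gene,
                "pathway_sizes": list(ds.config.pathway_sizes),
                "n_pathways": ds.config.n_pathways,
                "missing_rate": ds.config.missing_rate,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
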