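# Methods

## Analysis model

The pipeline targets pooled case–control GWAS data from several studies
genotyped on a common panel. The association model per SNP is additive
logistic regression, `logit P(case) = β·g + γ'x`, `g ∈ {0,1,2}` minor-allele
dosage, with covariates: age (years, linear), sex (0/1), DNA source (0/1),
smoking as three indicator contrasts against `never`, and study as K−1
indicators against the first (sorted) study label. Covariate missingness is
rejected at input validation; genotype missingness is handled complete-case
in the single-SNP Wald fits.

Two numerically distinct routes compute the same 1-df trend test:

* **Wald route** (`association.trend_test`): per-SNP maximum-likelihood fit
  (statsmodels GLM), reporting β, SE, OR, 95% CI and the Wald p. A
  likelihood-ratio p is available via `lrt=True`. Separation,
  non-convergence and constant dosages yield flagged results that gene
  statistics skip. Used for per-SNP report tables.
* **Score route** (`association.score_scan`): the efficient-score statistic
  `U = g'(y − μ̂)`, `V = g'Wg − g'WX (X'WX)⁻¹ X'Wg` with the covariate-only
  null model fitted once. Because the null fit never touches the genotype,
  the scan is a handful of dense matrix products over all SNPs — and
  permuting whole genotype rows against fixed (phenotype, covariates) is
  algebraically the same as permuting the residual/weight/design rows
  against fixed genotypes, so all B permutation replicates reuse one null
  fit. Wald and score tests agree to |Δlog10 p| well under 0.2 at the
  sample sizes used (tested). The pathway analysis uses the score route for
  *both* the observed and permuted statistics, which keeps the null
  exchangeable; mixing Wald-observed with score-permuted would not.

  In the scan, a SNP's missing dosages are mean-imputed (standard for
  score scans; keeps the computation a single GEMM and the observed and
  permuted statistics exchangeable). The synthetic generator's default
  missing rate is 0, so in the shipped experiments the two conventions
  coincide.

## Gene and pathway construction

Gene regions extend the coding span 20 kb beyond the 5′ end and 10 kb
beyond the 3′ end, strand-aware, 1-based inclusive bounds (BED input is
0-based half-open and converted on read). A SNP maps to every gene whose
region contains it. Gene sets come from GMT files; sets are filtered to
5–100 genes (inclusive) *before* intersecting with the genotyped gene list
— a set's identity is its curated size, while `N_H`/`L` downstream count
only genes with data. Set members absent from the coordinate table are
dropped with a logged count. Pathway overlap is reported as
`100·|A∩B| / min(N_A, N_B)` by default (keeps nested sets at 100%);
`union` and `mean` denominators are available.

Locus pooling is a union-find over genes: two genes join one unit iff they
share at least one mapped SNP, transitively closed; a unit's SNP set is the
union of its members'. Pooling is optional in the pipeline (off by
default) because the synthetic generator lays genes out with disjoint SNPs;
the packaged aromatic-amine worked example (11 genes → 7 units) exercises
it against a realistic shared-locus structure.

## Enrichment statistics

**Weighted KS (GSEA).** Genes sorted by `r_j = −log10 p_j` descending, ties
broken by gene id for determinism. Hit increment `r_j^p / N_R` with
`N_R = Σ_{j∈S} r_j^p` and weight `p = 1` by default (configurable; `p = 0`
reduces to the classical KS statistic and is invariant to monotone
transforms of `r`); miss decrement `1/(N − N_H)`. `ES` is the maximum of
the running sum — enrichment-only, since the question is
overrepresentation at the top. Degenerate cases: `N_H = 0` or `N` is
undefined (set skipped); all member weights zero returns the defined limit
`−N_H/(N − N_H)` with a warning. `N_R` is accumulated with `math.fsum` and
the scalar running sum strictly left-to-right, so the streaming
implementation is bit-identical to a brute-force recomputation; the
vectorized permutation path may differ by ~1 ulp and is tested against the
scalar path at 1e-12. The empirical p counts permutation `ES ≥` observed
(ties count — conservative); a zero count is displayed as `< 1/B`.

**ARTP.** `W(K) = Π_{k≤K} p_(k)` for every integer `K = 1..L` (the grid is
configurable for very large sets, but the default follows the
all-integers convention). Products are carried as `Σ log p`; all
comparisons are on log W. The two-level procedure treats the observed data
as replicate 0 of one exchangeable pool of `B+1` replicates:
`ŝ_i(K) = #{j : W_j(K) ≤ W_i(K)}/(B+1)` (self and ties counted, so never
zero), `minP_i = min_K ŝ_i(K)`, and the reported p-value is the pool rank
`#{i : minP_i ≤ minP_0}/(B+1)`. Exchangeability makes this a valid,
slightly conservative p-value; the asymmetric variant that ranks only the
observed against the permutations with a +1 correction is measurably
anti-conservative (null rejection ≈ 0.15 at α = 0.05 in our checks) and is
not used. `K*` reports the smallest K attaining the minimum. Fewer than 20
permutations triggers an instability warning.

**Shared permutation null.** One global shuffle of sample indices per
replicate, all from a single seeded generator; the same B replicates feed
every pathway, both enrichment methods, and the FDR — required for
cross-pathway comparability. Removing heterogeneity-flagged SNPs changes
only which SNPs feed each gene's minimum, not any SNP's p-value, so the
pre- and post-filter analyses legitimately consume the same SNP-level scan
and permutation replicates.

**Normalization and FDR.** Per pathway, `NS = (stat − mean_perm)/sd_perm`,
applied to the observed and every permutation value; pathways with zero
permutation SD are excluded with a flag. ARTP statistics are mapped to
`−log(minP)` first so both methods share the larger-is-more-significant
orientation. `FDR(s*) = [#{perm NS ≥ s*}/(B·M)] / [#{obs NS ≥ s*}/M]`,
clipped to [0,1], then monotonized with a cumulative minimum walked from
the least-significant threshold toward the most-significant
(Benjamini–Hochberg-style), so FDR never decreases as the threshold drops.

## Heterogeneity screen

Per SNP and study, the 2×2 allele-count table (alleles = genotype-weighted
counts, complete-case) gives `log OR = log(ad/bc)`,
`SE = √(1/a+1/b+1/c+1/d)`, with the Haldane–Anscombe +0.5 on every cell
when any cell is zero; a study with an empty margin is dropped for that
SNP. A per-study logistic fit is available behind `method="logistic"` and
agrees closely (tested). Inverse-variance fixed-effect pooling yields
Cochran's `Q` on k−1 df and `I² = max(0, 100·(Q − df)/Q)`. The removal
threshold is the p-value of `Q` — `I²` itself has no native p-value —
applied strictly (`< 0.2`) and globally (a flagged SNP leaves every gene).
A single-study SNP passes by convention. The 0.2 threshold is deliberately
liberal: under perfect homogeneity it removes ~20% of SNPs, trading power
for robustness against study artifacts; pre-filter results are therefore
always reported alongside.

## Synthetic data

The generator emulates the structure the analysis assumes, not human
genetics: genotypes come from a latent-Gaussian copula (per LD block, one
AR(1) vector per haplotype with correlation `within_block_rho`, default
0.5, thresholded at each SNP's MAF drawn uniformly from `maf_range`,
default [0.01, 0.5]; two haplotypes summed). Blocks sit 2 Mb apart on one
synthetic chromosome; within a block, genes occupy disjoint spans 50 kb
apart with their SNPs inside the coding region, so the 20 kb/10 kb rule
recovers exactly the intended SNP→gene map and genes never share SNPs.
Defaults mirror a five-study design of 3,532 cases and 5,120 controls;
causal per-allele log-ORs are specified per study (|log OR| ≲ 0.26,
matching the 0.77–1.27 OR range typical of reported susceptibility loci),
with a non-constant per-study vector defining a heterogeneous SNP.
Covariates are synthetic (age uniform 40–75, sex and DNA source Bernoulli
0.5, smoking 35/30/5/30% never/former/occasional/current) and configurable;
disease status follows the logistic model with study offsets, and the
case–control sample is drawn retrospectively from a cohort
`cohort_multiplier` (default 4) times the requested size, erroring with
advice when a quota cannot be met. All randomness flows from one seed,
recorded in the output metadata.

What the generator does **not** emulate: realistic haplotype structure
(coalescent, recombination maps), population stratification, genotyping
batch effects, covariate–genotype confounding, or genes that share SNPs.
Passing tests therefore demonstrate internal statistical correctness
(calibration, power, invariances) — not robustness to those real-data
complications.

## Experiment design and problem sizes

The shipped studies are sized to run in minutes on one core while keeping
Monte Carlo error small relative to the bands they check:

* **Null calibration** — five studies × (100+100), 2,000 SNPs, 500
  pathways, B = 200, α = 0.05, pooled over three replicate seeds (1,500
  pathway tests per method). The layout uses many small genes (2 SNPs
  each, 1,000 genes) and lean sets (5–10 genes) deliberately: ARTP is
  self-contained, so with heavy gene sharing all pathway tests move
  together within one observed scan and a single-replicate rejection rate
  estimates nothing (we measured seed-to-seed swings of ±0.03 with sets of
  5–50 genes over 400 genes, against a binomial SD of 0.01). The
  per-pathway p-value is exactly uniform either way — verified directly on
  iid inputs — the layout only controls the dependence of the *rate
  estimator*. GSEA, being competitive, is insensitive to this.
* **Embedded-pathway power** — 100 disjoint 10-gene pathways, one seeded
  with 5 causal genes at per-allele OR 1.3; five studies × (400+400);
  B = 200; rank of the seeded pathway recorded over 10 seeds.
* **Heterogeneity removal** — per-study log-ORs (+0.4, −0.4, +0.4, −0.4,
  0), five studies × (300+300), 20 seeds.
* **Concentrated vs diffuse** — 20-gene target pathway among 20; either
  one causal gene at OR 1.4 or ten at OR 1.10; five studies × (400+400);
  B = 200; median p over 20 seeds. This is a directional, qualitative
  contrast; with these effect sizes the concentrated direction (ARTP wins)
  is stable, while the diffuse margin (GSEA wins) is thinner and can
  invert for some seed sets — the honest reading is that the two tests are
  complementary, with the ordering sharpest when signals are extreme in
  their concentration.

## Known limitations

* The score-scan permutation engine assumes the covariate-only null fit is
  adequate for every SNP (exact only without genotype missingness; mean
  imputation otherwise).
* Permutation p-values are bounded below by 1/B (GSEA) and 1/(B+1) (ARTP);
  B must be chosen for the resolution needed.
* The FDR is a pooled-tail ratio estimator; with few pathways it is noisy
  and only its loose calibration is tested.
* Locus pooling treats any shared SNP as full redundancy; partial LD
  between genes that do not share SNPs is not pooled.
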