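# Methods

## Setting and model

The package analyses sequencing data from F1-hybrid mouse ES cells in which
the two parental genomes differ at known SNPs.  Two reciprocal crosses are
supported — BC (BL6 mother × cast father) and CB (cast mother × BL6 father) —
so the maternal allele corresponds to allele0 (the reference strain) in BC
and to allele1 in CB.  All coordinates are 0-based half-open internally;
1-based VCF positions are converted on input, BED stays 0-based.

### Allele assignment

Alignments are filtered to primary, non-multimapping records with
MAPQ ≥ 30.  A read end votes at every SNP its aligned blocks cover: bases
matching the reference-strain allele vote allele0, bases matching the
alternate-strain allele vote allele1, and bases matching neither (sequencing
errors) are ignored.  A read with votes for both strains is labelled
CONFLICT — a fourth internal category beyond the three-way classification,
since a mixed read cannot be evidence for either single allele — and is
discarded from allelic counts.  For paired-end data, one allele-certain end
assigns the fragment; pairs whose ends disagree, or with any CONFLICT end,
are discarded.  Spliced alignments carry multiple blocks, so SNPs under
skipped introns never vote.  Duplicate removal is coordinate-based on the
template's outer (chrom, start, end, strand) — a MarkDuplicates stand-in —
and is applied to ATAC/ChIP fragments only, not RNA-seq.

Fragments contribute to a gene when at least one aligned base overlaps the
gene's merged exon union; fragments overlapping exons of more than one gene
are counted for none (unambiguous assignment avoids double counting).

### Mapping-bias correction and allelic TPM

Reads matching the reference strain map slightly more efficiently even after
pseudo-genome construction.  The genome-wide correction factor is the ratio
of allele-informative autosomal fragments, r_m = N_A0/N_A1, computed **per
library** (bias is a property of a library, not of a clone); the corrected
allele0 proportion of gene i is p̂ᵢ₀ = nᵢ₀/(nᵢ₀ + r_m·nᵢ₁).  Genes with
nᵢ₀ + nᵢ₁ = 0 have undefined proportions and are excluded from allelic (not
diploid) analyses.  Diploid TPM uses the exon-union length in kb and the sum
of exonic fragments of counted genes as the library size; allelic TPMs are
the diploid TPM split by p̂ᵢ₀ and therefore sum exactly to it.  In male
samples the single X is maternal, so X-linked paternal TPM is masked to zero.
An "expressed" filter (> 1 TPM in at least one replicate) precedes
fold-change-style comparisons.

### Differential expression

A deliberately compact NB pipeline in the DESeq2 mould, since exact DESeq2
parity is a non-goal:

- **Size factors**: median of log-ratios to per-gene geometric means over
  genes expressed in every sample, rescaled to geometric mean 1.
- **Dispersion**: per-gene method-of-moments estimate from the pooled
  within-group variance of normalized counts (var = μ·mean(1/s) + αμ²),
  a parametric trend α(μ) = a₀ + a₁/μ fitted by trimmed least squares, and
  log-scale shrinkage of the raw estimate toward the trend with weight 0.8.
  The heavy weight reflects that with 2–3 replicates per group the moment
  estimate carries ~4 residual degrees of freedom; genes whose raw estimate
  is non-positive take the trend value outright.  Under replicated null
  simulations (2,000 genes, 3 vs 3, dispersion 0.1) this combination holds
  the empirical type-I error near the nominal 0.05 — both for constant and
  for gene-varying dispersions — where weaker shrinkage is anticonservative
  and a t reference with 4 df is overconservative.
- **Wald test**: the log ratio of normalized group means (0.5 pseudocount,
  stabilizing zeros in allelic counts) over its delta-method NB standard
  error, referred to the standard normal; Benjamini–Hochberg FDR.
- **Calls**: FDR < 0.05 and |log2FC| ≥ log2(1.5); off-target deletion genes
  can be excluded via a list.

Allelic differential calls run the same test independently on maternal and
paternal counts with allele-specific size factors (per-allele runs rather
than a joint interaction design — the simpler contract, and the one the
group definitions imply).  A post filter removes genes whose allelic TPM
stays below 1 in every sample of the contrast, as do masked X-paternal
entries.  Groups: down-regulated DEGs are A (maternal only), B (paternal
only), C (both); up-regulated are D/E/F.  {A,B,C} partition the allelic
down set; a gene can simultaneously carry an up and a down group (e.g.
maternal-up + paternal-down = D and B).  The allele-specific share of a
direction is (specific)/(specific + biallelic), reported as an integer
percentage, rounded half-up.

The relaxed cross-comparison calls a gene down in one cross when
mean wt TPM / mean KO TPM ≥ 1.25 (arithmetic means across clones) and
intersects the per-cross lists.  The 1.25 threshold is applied on the TPM
ratio scale, not as a log2 difference — the two phrasings in circulation
disagree, and the ratio reading is the one consistent with a "1.25
fold change in TPM value".  The 0.5 TPM pseudocount acts here as a floor on
the denominator (ratio = high / max(low, 0.5)) rather than an additive
offset: an additive offset would silently move the 1.25 boundary for
low-expressed genes (10 vs 8 TPM is exactly 1.25-fold and should be called),
while the floor only guards division by zero.

### Sex bias

Sex-biased: ≥ 2-fold difference of mean TPM between sexes with a two-sided
**equal-variance Student's t-test** p ≤ 0.05 (the literal test named; Welch
available behind a flag).  Fold ratios add a 0.5 TPM pseudocount to both
means.  **Loss** after knockout is fold-only: a wild-type-biased gene whose
female-wt vs male-KO ratio (in the direction of the wild-type bias) falls
below 2 — no p-value, matching the definition's parenthetical form, which
genuinely differs from the gain criterion.  For male-biased genes the
comparison mirrors to male-KO over female-wt (female KO data are not part of
the design).  **Gain** in a previously unbiased gene applies the full biased
criterion (fold and p) to the post-KO comparison.  Loss and gain are
mutually exclusive per gene since they apply to disjoint wild-type classes.
Quantile normalization (per-rank column means; ties share the mean of their
would-be quantile values via average ranks) supports comparisons against
externally processed wild-type matrices.  Allelic bias in wild type is a
≥ 2-fold difference between mean maternal and paternal TPM.

### Chromatin

Promoters are symmetric TSS ± 2 kb windows, clipped at chromosome bounds;
strand does not move the window.  Coverage is fragment-level (reproducible
without coverage-track conventions): a fragment counts toward every region
it overlaps by ≥ 1 bp, so overlapping regions are independent and
maternal + paternal + uncertain = diploid per region.  Depth scaling is
fragments per million assigned fragments; ChIP signal is input-normalized as
(chip + 1)/(input + 1) on depth-scaled values (pseudocount 1 avoids division
by zero at empty promoters).  Quantile normalization across alleles and
lines assumes comparable promoter coverage distributions.  Per-group shifts
of log2(KO/wt) are tested with a two-sided Wilcoxon signed-rank against
zero (the standard robust choice for paired ratio shifts; a t-test variant
is not exposed because the signed-rank covers the use case); a degenerate
all-equal input is flagged rather than tested.

## Synthetic data generator

`SimConfig` encodes the emulated study design; the defaults are the study
conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| genes / chromosomes | 2,000 on 2 autosomes + X (5% X-linked) | desk-scale genome with both chromosome classes |
| samples per cross | 2 wt M, 3 KO M, 2 wt F | the emulated clone design |
| read length / fragment | 75 bp, 250 ± 25 bp | short-read library geometry |
| SNP density | 0.005 /bp | gives most genes informative exonic SNPs ("most genes" informative) |
| informative fraction | 0.20 | ~11% + ~9% of fragments allele-certain |
| mapping bias r_true | 1.2 | the ratio implied by the 11%/9% split |
| NB dispersion | 0.05 | clonal ES replicates are tight |
| KO effect | 4-fold, 1% of genes per group A–F | clear allelic effects at desk-scale power |
| sex bias | 3-fold; 5% female-, 2% male-biased; loss prob. 0.35/0.25; 0.5% gains | mirrors the female-skewed biased-gene accounting |
| imprinting | 1% of genes, maternal fraction 0.95 | canonical maternally expressed cluster behaviour |
| depth | 10⁶ fragments/sample (counts level) | enough informative counts for allelic tests |

Count-level simulation draws maternal and paternal NB counts around the
planted means (KO effects applied to the allele(s) the gene's group
dictates; sex effects by sex/genotype; X-linked genes fully maternal in
males), sums them into diploid counts, and thins allele-informative counts
binomially with the mapping bias tilting recovery (√r_true up for allele0,
√r_true down for allele1), so Σn₀/Σn₁ over autosomes estimates r_true.
Planted effects (groups, sex bias, imprinting) are placed on genes in the
upper half of the expression distribution: effects on near-silent genes are
unobservable by construction and empirical group labels only exist for
genes passing the TPM filter, so planting them would measure the expression
floor, not the method.  Read-level simulation additionally samples spliced
paired-end reads from the chosen haplotype sequence (reference or
pseudo-genome), with configurable sequencing-error and coordinate-duplicate
rates, written as valid SAM.  Sex-bias "loss" is simulated as the KO male
reverting to the female expression level, which also makes those genes
genuine biallelic DEGs — so the C and F groups in a full run contain the
sex-collapse genes on top of the planted ones, as they would in real data.
Chromatin simulation draws NB promoter counts per allele with H3K27me3
gains (3-fold) and accessibility losses (2-fold) on the affected allele(s)
of down-group genes, the opposite for up groups, and a flat input.
Everything is deterministic under the seed.

What the generator does **not** emulate: alignment errors and multimapping
(reads are emitted pre-aligned to their true origin), GC/positional bias,
isoform structure, cross-gene count correlation, and strain-dependent
expression differences beyond the mapping bias.  Passing tests therefore
validate the statistical machinery and the bookkeeping, not robustness to
alignment artefacts.

## Verification experiments and problem sizes

The test suite and `scripts/acceptance.py` run the same experiments (module
`hybridase.evaluation`): proportion recovery over a maternal-fraction grid
(2,000 genes, 600 informative fragments/gene, bias 1.3); classifier
agreement with a brute-force per-base oracle (10⁴ reads); NB null
calibration (10 replicates of 2,000 genes, 3 vs 3, dispersion 0.1) and
fourfold power (mean count 200, dispersion 0.05); end-to-end group recovery
under the default configuration; and the maternal H3K27me3 shift pattern.
These sizes keep the whole suite under a minute of compute while leaving
the stochastic checks comfortable margins.  Read-level tests use smaller
genomes (tens of genes, ~10⁴ fragments) because SAM synthesis is the slow
path.

## Known limitations

- The NB test is a documented stand-in, not DESeq2: no Cook's-distance
  outlier handling, no independent filtering, no LFC shrinkage; p-values
  for very low counts lean on the 0.5 pseudocount.
- Classification assumes one alignment set plus a SNP table; it does not
  verify uniqueness against both haplotype genomes separately, which a
  dual-mapping workflow would.
- Quantile normalization with heavy ties across columns yields tie-averaged
  values whose multisets can differ slightly between columns; for the
  continuous coverage/TPM matrices it is exact.
- The enhancer catalogue is consumed as user-provided BED regions; deriving
  enhancers from histone data is out of scope, as are peak calling, GO
  enrichment, and isoform-level quantification.
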