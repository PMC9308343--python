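"""Synthetic F1-hybrid data generator with ground truth.

Emulates the statistical structure of an F1-hybrid ES-cell knockout study on
reciprocal crosses: biallelic genes carrying strain SNPs in their exons, a
maternal fraction per gene (0.5 for ordinary genes, near 1 for maternally
imprinted ones, 1 for X-linked genes in males), a planted strain mapping bias
r_true acting on allele-informative read recovery, knockout effects confined
to the maternal allele, the paternal allele, or both (allelic groups A-F),
sex-biased expression with probabilistic loss after knockout, and allelic
promoter chromatin signal with group-restricted H3K27me3 / accessibility
shifts.  Everything is deterministic under the seed.

Two levels are generated: count-level tables (fast, for statistical tests)
and read-level SAM alignments sampled from the two haplotype sequences (to
exercise parsing and SNP classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .genome import SnpRecord, SnpIndex, build_pseudo_genome, build_snp_index
from .models import GeneModel
from .quantify import SampleMeta

GROUP_ALLELES = {
    "A": ("maternal",),
    "B": ("paternal",),
    "C": ("maternal", "paternal"),
    "D": ("maternal",),
    "E": ("paternal",),
    "F": ("maternal", "paternal"),
}
DOWN_GROUPS = ("A", "B", "C")
UP_GROUPS = ("D", "E", "F")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic hybrid experiment.

    Defaults mirror the emulated study: 75 bp reads, MAPQ-clean unique
    alignments, ~20% of fragments allele-informative with a mild
    reference-strain advantage (r_true = 1.2, matching the reported ~11% vs
    ~9% split), NB-distributed counts, fourfold knockout effects restricted
    to the allele(s) of each gene's group, threefold sex biases with a 35% /
    25% chance of loss after knockout, and a small maternally imprinted
    class.  Two wild-type and three knockout male clones per cross, plus two
    wild-type females.
    """

    seed: int = 0
    # genome / reads level
    n_chromosomes: int = 3  # last one is "X"
    chrom_length: int = 1_200_000
    n_genes: int = 2000
    exons_per_gene: int = 3
    exon_length: int = 200
    intron_length: int = 150
    snp_density: float = 0.005
    read_length: int = 75
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    error_rate: float = 0.0
    duplicate_rate: float = 0.0
    # counts level
    depth: int = 1_000_000  # fragments per sample
    informative_read_fraction: float = 0.20
    r_true: float = 1.2
    nb_dispersion: float = 0.05
    base_expression_sigma: float = 1.0
    # planted biology
    group_fraction: float = 0.01  # of genes, per group A-F
    ko_effect_fold: float = 4.0
    female_biased_fraction: float = 0.05
    male_biased_fraction: float = 0.02
    sex_bias_fold: float = 3.0
    loss_probability_female: float = 0.35
    loss_probability_male: float = 0.25
    gain_fraction: float = 0.005
    imprinted_fraction: float = 0.01
    imprinted_maternal_fraction: float = 0.95
    x_gene_fraction: float = 0.05
    # planted effects are placed on expressed genes: eligibility floor as an
    # expression quantile (effects on near-silent genes are unobservable and
    # empirical group labels only exist for genes passing the TPM filter)
    planted_expression_quantile: float = 0.5
    # samples
    crosses: Tuple[str, ...] = ("BC", "CB")
    n_wt_male: int = 2
    n_ko_male: int = 3
    n_wt_female: int = 2
    # chromatin
    chromatin_mean: float = 200.0
    chromatin_dispersion: float = 0.05
    chip_effect_fold: float = 3.0
    atac_effect_fold: float = 2.0
    input_mean: float = 200.0

    def __post_init__(self) -> None:
        fractions = [
            6 * self.group_fraction,
            self.female_biased_fraction,
            self.male_biased_fraction,
            self.gain_fraction,
            self.imprinted_fraction,
        ]
        if any(f < 0 for f in fractions) or sum(fractions) > 1:
            raise ValueError("planted gene fractions must be in [0,1] and sum <= 1")
        if not 0 < self.informative_read_fraction <= 1:
            raise ValueError("informative_read_fraction must be in (0,1]")
        if self.snp_density >= 1:
            raise ValueError("snp_density must be < 1")
        if self.r_true <= 0:
            raise ValueError("r_true must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


# ---------------------------------------------------------------------------
# Reference and genes


def chrom_names(config: SimConfig) -> List[str]:
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes - 1)]
    names.append("chrX")
    return names


def simulate_reference(config: SimConfig) -> Tuple[Dict[str, str], List[SnpRecord]]:
    """Random chromosome sequences plus Bernoulli-placed strain SNPs."""
    rng = config.rng(1)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences: Dict[str, str] = {}
    snps: List[SnpRecord] = []
    for chrom in chrom_names(config):
        seq_idx = rng.integers(0, 4, size=config.chrom_length)
        seq = bases[seq_idx].tobytes().decode("ascii")
        sequences[chrom] = seq
        if config.snp_density > 0:
            hits = np.flatnonzero(
                rng.random(config.chrom_length) < config.snp_density
            )
            for pos in hits:
                ref = seq[pos]
                alt = "ACGT"[(("ACGT".index(ref)) + rng.integers(1, 4)) % 4]
                snps.append(SnpRecord(chrom, int(pos), ref, alt))
    return sequences, snps


def simulate_genes(config: SimConfig, reference: Mapping[str, str]) -> List[GeneModel]:
    """Non-overlapping multi-exon genes laid across the chromosomes.

    Genes are placed sequentially with random gaps; a configured fraction
    lands on chrX, the remainder round-robins over the autosomes.  Exon
    unions are always at least one read long.
    """
    rng = config.rng(2)
    if config.exons_per_gene * config.exon_length < config.read_length:
        raise ValueError("exon union shorter than one read")
    names = chrom_names(config)
    autosomes = names[:-1]
    n_x = int(round(config.n_genes * config.x_gene_fraction))
    assignment = [names[-1]] * n_x + [
        autosomes[i % len(autosomes)] for i in range(config.n_genes - n_x)
    ]
    cursor = {name: 0 for name in names}
    span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    genes: List[GeneModel] = []
    for i, chrom in enumerate(assignment):
        start = cursor[chrom] + int(rng.integers(50, 200))
        if start + span > len(reference[chrom]):
            raise ValueError(
                f"cannot place {config.n_genes} genes of span {span} bp on "
                f"{config.n_chromosomes} x {config.chrom_length} bp chromosomes"
            )
        exons = []
        pos = start
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_length))
            pos += config.exon_length + config.intron_length
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:05d}", chrom, strand, exons))
        cursor[chrom] = start + span
    return genes


# ---------------------------------------------------------------------------
# Truth and counts


def make_samples(config: SimConfig) -> List[SampleMeta]:
    samples: List[SampleMeta] = []
    for cross in config.crosses:
        for i in range(config.n_wt_male):
            samples.append(SampleMeta(f"{cross}_wt_M{i + 1}", cross, "M", "wt"))
        for i in range(config.n_ko_male):
            samples.append(SampleMeta(f"{cross}_KO_M{i + 1}", cross, "M", "KO"))
        for i in range(config.n_wt_female):
            samples.append(SampleMeta(f"{cross}_wt_F{i + 1}", cross, "F", "wt"))
    return samples


def simulate_truth(config: SimConfig, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene planted parameters: maternal fraction, group, sex bias,
    loss/gain flags, and base expression weight."""
    rng = config.rng(3)
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    chroms = np.array([g.chrom for g in genes])
    autosomal = np.array([g.is_autosomal for g in genes])

    base = rng.lognormal(mean=0.0, sigma=config.base_expression_sigma, size=n)
    base_mean = config.depth * base / base.sum()

    group = np.full(n, "none", dtype=object)
    sex_bias = np.full(n, "none", dtype=object)
    sex_loss = np.zeros(n, dtype=bool)
    sex_gain = np.full(n, "none", dtype=object)
    imprinted = np.zeros(n, dtype=bool)
    f = np.full(n, 0.5)

    floor = np.quantile(base_mean, config.planted_expression_quantile)
    pool = rng.permutation(np.flatnonzero(autosomal & (base_mean >= floor)))
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        if cursor + count > len(pool):
            raise ValueError("planted fractions exceed the eligible gene pool")
        sel = pool[cursor : cursor + count]
        cursor += count
        return sel

    per_group = int(round(config.group_fraction * n))
    for name in DOWN_GROUPS + UP_GROUPS:
        group[take(per_group)] = name
    n_female = int(round(config.female_biased_fraction * n))
    n_male = int(round(config.male_biased_fraction * n))
    idx_f = take(n_female)
    idx_m = take(n_male)
    sex_bias[idx_f] = "female"
    sex_bias[idx_m] = "male"
    sex_loss[idx_f] = rng.random(n_female) < config.loss_probability_female
    sex_loss[idx_m] = rng.random(n_male) < config.loss_probability_male
    n_gain = int(round(config.gain_fraction * n))
    idx_g = take(n_gain)
    sex_gain[idx_g] = np.where(rng.random(n_gain) < 0.5, "female", "male")
    n_imp = int(round(config.imprinted_fraction * n))
    idx_i = take(n_imp)
    imprinted[idx_i] = True
    f[idx_i] = config.imprinted_maternal_fraction

    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "autosomal": autosomal,
            "base_mean": base_mean,
            "f": f,
            "group": group,
            "sex_bias": sex_bias,
            "sex_loss": sex_loss,
            "sex_gain": sex_gain,
            "imprinted": imprinted,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return truth


def _expected_means(
    truth: pd.DataFrame, meta: SampleMeta, config: SimConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Planted maternal and paternal mean counts for one sample."""
    mu = truth["base_mean"].to_numpy().copy()
    group = truth["group"].to_numpy()
    sex_bias = truth["sex_bias"].to_numpy()
    sex_loss = truth["sex_loss"].to_numpy()
    sex_gain = truth["sex_gain"].to_numpy()
    f = truth["f"].to_numpy().copy()
    on_x = (truth["chrom"].to_numpy() == "chrX")

    if meta.sex == "M":
        female_low = (sex_bias == "female")
        male_high = (sex_bias == "male")
        if meta.genotype == "KO":
            # a lost gene collapses to the female level (ratio ~1)
            mu[female_low & ~sex_loss] /= config.sex_bias_fold
            mu[male_high & ~sex_loss] *= config.sex_bias_fold
            mu[sex_gain == "female"] /= config.sex_bias_fold
            mu[sex_gain == "male"] *= config.sex_bias_fold
        else:
            mu[female_low] /= config.sex_bias_fold
            mu[male_high] *= config.sex_bias_fold
        f = np.where(on_x, 1.0, f)  # single maternal X in males

    mu_mat = mu * f
    mu_pat = mu * (1.0 - f)
    if meta.genotype == "KO":
        for name in DOWN_GROUPS:
            hit = group == name
            if "maternal" in GROUP_ALLELES[name]:
                mu_mat[hit] /= config.ko_effect_fold
            if "paternal" in GROUP_ALLELES[name]:
                mu_pat[hit] /= config.ko_effect_fold
        for name in UP_GROUPS:
            hit = group == name
            if "maternal" in GROUP_ALLELES[name]:
                mu_mat[hit] *= config.ko_effect_fold
            if "paternal" in GROUP_ALLELES[name]:
                mu_pat[hit] *= config.ko_effect_fold
    return mu_mat, mu_pat


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, variance = mean + alpha*mean^2) via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=np.maximum(mean, 1e-300) * alpha)
    lam[mean <= 0] = 0.0
    return rng.poisson(lam)


@dataclass
class SimCounts:
    """Count-level simulation output with ground truth."""

    config: SimConfig
    samples: List[SampleMeta]
    truth: pd.DataFrame
    diploid: pd.DataFrame  # genes x samples
    maternal: pd.DataFrame  # true maternal haplotype counts, genes x samples
    paternal: pd.DataFrame
    allelic: Dict[str, pd.DataFrame]  # sample -> n0/n1/n_uncertain/n_total

    def sample(self, sample_id: str) -> SampleMeta:
        for meta in self.samples:
            if meta.sample_id == sample_id:
                return meta
        raise KeyError(sample_id)

    def samples_where(self, **conditions) -> List[SampleMeta]:
        out = []
        for meta in self.samples:
            if all(getattr(meta, key) == val for key, val in conditions.items()):
                out.append(meta)
        return out


def simulate_counts(
    config: SimConfig,
    genes: Optional[Sequence[GeneModel]] = None,
    truth: Optional[pd.DataFrame] = None,
) -> SimCounts:
    """Draw diploid and allele-informative counts for every sample.

    Maternal and paternal haplotype counts are NB draws around the planted
    means; the diploid count is their sum.  Allele-informative counts are a
    binomial thinning at the informative-read fraction, with the mapping bias
    r_true tilting recovery toward allele0 (sqrt(r_true) up for allele0,
    sqrt(r_true) down for allele1).
    """
    if genes is None:
        genes = simulate_genes(config, _lengths_only(config))
    if truth is None:
        truth = simulate_truth(config, genes)
    rng = config.rng(4)
    samples = make_samples(config)
    alpha = config.nb_dispersion
    p0_keep = config.informative_read_fraction * np.sqrt(config.r_true)
    p1_keep = config.informative_read_fraction / np.sqrt(config.r_true)
    if p0_keep > 1 or p1_keep > 1:
        raise ValueError("informative fraction times bias exceeds 1")

    diploid = {}
    maternal = {}
    paternal = {}
    allelic: Dict[str, pd.DataFrame] = {}
    for meta in samples:
        mu_mat, mu_pat = _expected_means(truth, meta, config)
        c_mat = _nb_draw(rng, mu_mat, alpha)
        c_pat = _nb_draw(rng, mu_pat, alpha)
        if meta.maternal_allele == 0:
            c_a0, c_a1 = c_mat, c_pat
        else:
            c_a0, c_a1 = c_pat, c_mat
        n0 = rng.binomial(c_a0, p0_keep)
        n1 = rng.binomial(c_a1, p1_keep)
        total = c_mat + c_pat
        table = pd.DataFrame(
            {
                "n0": n0,
                "n1": n1,
                "n_uncertain": total - n0 - n1,
                "n_total": total,
            },
            index=truth.index,
        )
        allelic[meta.sample_id] = table
        diploid[meta.sample_id] = total
        maternal[meta.sample_id] = c_mat
        paternal[meta.sample_id] = c_pat

    return SimCounts(
        config=config,
        samples=samples,
        truth=truth,
        diploid=pd.DataFrame(diploid, index=truth.index),
        maternal=pd.DataFrame(maternal, index=truth.index),
        paternal=pd.DataFrame(paternal, index=truth.index),
        allelic=allelic,
    )


def _lengths_only(config: SimConfig) -> Dict[str, str]:
    """Placeholder 'sequences' giving simulate_genes chromosome lengths
    without generating actual sequence (counts-level shortcut)."""
    return {name: "N" * config.chrom_length for name in chrom_names(config)}


# ---------------------------------------------------------------------------
# Read-level simulation


def _union_offsets(gene: GeneModel) -> Tuple[np.ndarray, np.ndarray]:
    starts = np.array([s for s, _ in gene.exons])
    lengths = np.array([e - s for s, e in gene.exons])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return starts, offsets


def _transcript_to_blocks(
    gene: GeneModel, t_start: int, length: int
) -> List[Tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    blocks = []
    remaining = length
    pos = t_start
    starts, offsets = _union_offsets(gene)
    lengths = [e - s for s, e in gene.exons]
    for (exon_start, exon_len, offset) in zip(starts, lengths, offsets):
        if remaining <= 0:
            break
        if pos >= offset + exon_len:
            continue
        local = max(pos - offset, 0)
        take = min(exon_len - local, remaining)
        blocks.append((int(exon_start + local), int(exon_start + local + take)))
        remaining -= take
        pos += take
    if remaining > 0:
        raise ValueError("fragment extends past the exon union")
    return blocks


def _blocks_to_cigar(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    cigar = []
    for i, (start, end) in enumerate(blocks):
        if i:
            gap = start - blocks[i - 1][1]
            if gap > 0:
                cigar.append((3, gap))  # N
        cigar.append((0, end - start))  # M
    return cigar


def _spliced_sequence(seq: str, blocks: Sequence[Tuple[int, int]]) -> str:
    return "".join(seq[s:e] for s, e in blocks)


def simulate_alignments(
    config: SimConfig,
    reference: Mapping[str, str],
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    out_dir: str | Path,
    samples: Optional[Sequence[SampleMeta]] = None,
    fragments_per_gene: Optional[int] = None,
) -> Dict[str, Path]:
    """Write one paired-end SAM per sample, sampled from the haplotypes.

    Each fragment picks the maternal or paternal haplotype according to the
    gene's planted maternal fraction (and sample effects), draws a fragment
    length ~ Normal(mean, sd) inside the exon union, and emits a spliced read
    pair with valid CIGARs.  Sequencing errors and coordinate-identical
    duplicates are planted at the configured rates.  Returns sample -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pseudo = build_pseudo_genome(reference, list(snps))
    rng = config.rng(5)
    if samples is None:
        samples = make_samples(config)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in reference.items()
            ],
        }
    )
    paths: Dict[str, Path] = {}
    for meta in samples:
        path = out_dir / f"{meta.sample_id}.sam"
        mu_mat, mu_pat = _expected_means(truth, meta, config)
        weight = mu_mat + mu_pat
        if fragments_per_gene is not None:
            expected = np.full(len(genes), float(fragments_per_gene))
        else:
            expected = config.depth * weight / weight.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            f_eff = np.where(weight > 0, mu_mat / weight, 0.5)
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            serial = 0
            for gi, gene in enumerate(genes):
                n_frag = rng.poisson(expected[gi])
                union = gene.exon_union_length
                for _ in range(n_frag):
                    maternal = rng.random() < f_eff[gi]
                    if meta.maternal_allele == 0:
                        use_alt = not maternal
                    else:
                        use_alt = maternal
                    haplotype = pseudo if use_alt else reference
                    frag_len = int(
                        np.clip(
                            rng.normal(config.fragment_mean, config.fragment_sd),
                            config.read_length,
                            union,
                        )
                    )
                    t_start = int(rng.integers(0, union - frag_len + 1))
                    name = f"{meta.sample_id}.frag{serial}"
                    serial += 1
                    _emit_pair(
                        sam, header, rng, config, haplotype, gene, name,
                        t_start, frag_len,
                    )
                    if rng.random() < config.duplicate_rate:
                        _emit_pair(
                            sam, header, rng, config, haplotype, gene,
                            f"{name}.dup", t_start, frag_len,
                        )
        paths[meta.sample_id] = path
    return paths


def _emit_pair(sam, header, rng, config, haplotype, gene, name, t_start, frag_len):
    read_len = min(config.read_length, frag_len)
    b1 = _transcript_to_blocks(gene, t_start, read_len)
    b2 = _transcript_to_blocks(gene, t_start + frag_len - read_len, read_len)
    seq = haplotype[gene.chrom]
    for which, blocks, mate_blocks, reverse in (
        (1, b1, b2, False),
        (2, b2, b1, True),
    ):
        aln = pysam.AlignedSegment(header)
        aln.query_name = name
        read_seq = _spliced_sequence(seq, blocks).upper()
        if config.error_rate > 0:
            read_seq = _apply_errors(read_seq, config.error_rate, rng)
        aln.query_sequence = read_seq
        aln.query_qualities = pysam.qualitystring_to_array("I" * len(read_seq))
        aln.reference_name = gene.chrom
        aln.reference_start = blocks[0][0]
        aln.cigartuples = _blocks_to_cigar(blocks)
        aln.mapping_quality = 60
        aln.is_paired = True
        aln.is_proper_pair = True
        aln.is_read1 = which == 1
        aln.is_read2 = which == 2
        aln.is_reverse = reverse
        aln.mate_is_reverse = not reverse
        aln.next_reference_name = gene.chrom
        aln.next_reference_start = mate_blocks[0][0]
        span_start = min(blocks[0][0], mate_blocks[0][0])
        span_end = max(blocks[-1][1], mate_blocks[-1][1])
        aln.template_length = (span_end - span_start) * (-1 if reverse else 1)
        aln.set_tag("NH", 1)
        sam.write(aln)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = "ACGT"[(("ACGT".index(arr[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Chromatin simulation


@dataclass
class SimChromatin:
    """Count-level allelic promoter signal for ChIP, ATAC, and input.

    Each assay maps sample_id -> DataFrame (index gene_id, columns
    'maternal'/'paternal') of promoter fragment counts.
    """

    chip: Dict[str, pd.DataFrame]
    atac: Dict[str, pd.DataFrame]
    input_: Dict[str, pd.DataFrame]
    samples: List[SampleMeta]
    truth: pd.DataFrame


def simulate_chromatin(
    config: SimConfig,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    samples: Optional[Sequence[SampleMeta]] = None,
) -> SimChromatin:
    """Promoter-level allelic chromatin counts with planted KO shifts.

    In knockout samples, genes of the down groups gain H3K27me3 and lose
    accessibility on the allele(s) their group dictates; up groups shift the
    opposite way.  The input control is flat.  One wt and one KO male sample
    per cross by default (the assay design of the emulated study).
    """
    rng = config.rng(6)
    if samples is None:
        samples = []
        for cross in config.crosses:
            samples.append(SampleMeta(f"{cross}_wt_M1", cross, "M", "wt"))
            samples.append(SampleMeta(f"{cross}_KO_M1", cross, "M", "KO"))
    base = rng.lognormal(
        mean=np.log(config.chromatin_mean), sigma=0.5, size=len(genes)
    )
    group = truth["group"].to_numpy()
    chip, atac, input_ = {}, {}, {}
    gene_index = truth.index
    for meta in samples:
        chip_mu = np.column_stack([base / 2, base / 2])  # maternal, paternal
        atac_mu = chip_mu.copy()
        if meta.genotype == "KO":
            for name, direction in [(g, "down") for g in DOWN_GROUPS] + [
                (g, "up") for g in UP_GROUPS
            ]:
                hit = group == name
                cols = [
                    0 if allele == "maternal" else 1
                    for allele in GROUP_ALLELES[name]
                ]
                for col in cols:
                    if direction == "down":
                        chip_mu[hit, col] *= config.chip_effect_fold
                        atac_mu[hit, col] /= config.atac_effect_fold
                    else:
                        chip_mu[hit, col] /= config.chip_effect_fold
                        atac_mu[hit, col] *= config.atac_effect_fold
        alpha = config.chromatin_dispersion
        chip[meta.sample_id] = pd.DataFrame(
            {
                "maternal": _nb_draw(rng, chip_mu[:, 0], alpha),
                "paternal": _nb_draw(rng, chip_mu[:, 1], alpha),
            },
            index=gene_index,
        )
        atac[meta.sample_id] = pd.DataFrame(
            {
                "maternal": _nb_draw(rng, atac_mu[:, 0], alpha),
                "paternal": _nb_draw(rng, atac_mu[:, 1], alpha),
            },
            index=gene_index,
        )
        flat = np.full(len(genes), config.input_mean)
        input_[meta.sample_id] = pd.DataFrame(
            {
                "maternal": _nb_draw(rng, flat / 2, alpha),
                "paternal": _nb_draw(rng, flat / 2, alpha),
            },
            index=gene_index,
        )
    return SimChromatin(
        chip=chip, atac=atac, input_=input_, samples=list(samples), truth=truth
    )
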