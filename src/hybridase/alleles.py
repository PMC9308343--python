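"""SNP-based assignment of alignments to parental alleles.

Filtered alignments (unique, MAPQ >= 30) are classified by the SNP bases they
cover: reads carrying only reference-strain (allele0/BL6) SNP bases, only
alternate-strain (allele1/cast) bases, or no informative SNP base at all
(allele-uncertain).  A read with bases supporting both strains gets an internal
CONFLICT label and is excluded from allelic counts.  For paired-end data a
fragment inherits the call of its allele-certain end; pairs whose ends disagree
are discarded.  Per-gene exonic tallies of the three classes and the
genome-wide autosomal mapping-bias ratio r_m = N_A0/N_A1 feed the
bias-corrected allelic expression decomposition.
"""

from __future__ import annotations

import enum
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome import SnpIndex
from .models import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MAPQ = 30


class AlleleCall(enum.Enum):
    ALLELE0 = "allele0"
    ALLELE1 = "allele1"
    UNCERTAIN = "uncertain"
    CONFLICT = "conflict"


class FragmentCall(enum.Enum):
    ALLELE0 = "allele0"
    ALLELE1 = "allele1"
    UNCERTAIN = "uncertain"
    DISCARD = "discard"


@dataclass
class AlignedRead:
    """One aligned read end with its per-block reference placement.

    ``blocks`` holds (read_offset, ref_start, length) triples covering the
    aligned (M/=/X) stretches; skipped introns (N) and clipped bases produce
    gaps between blocks, so SNPs under them never vote.
    """

    read_id: str
    chrom: str
    start: int
    blocks: List[Tuple[int, int, int]]
    sequence: str
    mapq: int
    mate_flag: str = "unpaired"  # first | second | unpaired
    is_reverse: bool = False
    is_duplicate: bool = False
    is_unique: bool = True

    @property
    def end(self) -> int:
        return max(ref_start + length for _, ref_start, length in self.blocks)

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedRead":
        blocks: List[Tuple[int, int, int]] = []
        read_off = 0
        ref_pos = aln.reference_start
        for op, length in aln.cigartuples or []:
            if op in (0, 7, 8):  # M, =, X consume both
                blocks.append((read_off, ref_pos, length))
                read_off += length
                ref_pos += length
            elif op in (1, 4):  # I, S consume read only
                read_off += length
            elif op in (2, 3):  # D, N consume reference only
                ref_pos += length
        nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
        unique = not aln.is_secondary and not aln.is_supplementary and nh == 1
        if aln.is_paired:
            mate = "first" if aln.is_read1 else "second"
        else:
            mate = "unpaired"
        return cls(
            read_id=aln.query_name,
            chrom=aln.reference_name,
            start=aln.reference_start,
            blocks=blocks,
            sequence=aln.query_sequence or "",
            mapq=aln.mapping_quality,
            mate_flag=mate,
            is_reverse=aln.is_reverse,
            is_duplicate=aln.is_duplicate,
            is_unique=unique,
        )


@dataclass
class Fragment:
    """An allele-assigned sequencing fragment (read pair or single end)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    call: FragmentCall
    blocks: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class MappingBias:
    """Genome-wide allele0/allele1 mapping ratio over autosomal genes."""

    n_a0: int
    n_a1: int

    @property
    def r_m(self) -> float:
        return self.n_a0 / self.n_a1


def filter_alignments(
    reads: Iterable[AlignedRead], mapq_min: int = DEFAULT_MAPQ
) -> Iterator[AlignedRead]:
    """Keep uniquely mapped reads with MAPQ >= mapq_min, preserving order."""
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    for read in reads:
        if read.is_unique and read.mapq >= mapq_min:
            yield read


def classify_read(read: AlignedRead, snps: SnpIndex) -> AlleleCall:
    """Classify one read end by the SNP bases it covers.

    All covered SNP bases matching ref_allele -> ALLELE0; all matching
    alt_allele -> ALLELE1; support for both -> CONFLICT.  A base matching
    neither allele (sequencing error) is ignored; with no informative SNP base
    the read is UNCERTAIN.
    """
    saw0 = saw1 = False
    for read_off, ref_start, length in read.blocks:
        for snp in snps.overlapping(read.chrom, ref_start, ref_start + length):
            base = read.sequence[read_off + (snp.pos - ref_start)].upper()
            if base == snp.ref_allele:
                saw0 = True
            elif base == snp.alt_allele:
                saw1 = True
    if saw0 and saw1:
        return AlleleCall.CONFLICT
    if saw0:
        return AlleleCall.ALLELE0
    if saw1:
        return AlleleCall.ALLELE1
    return AlleleCall.UNCERTAIN


def assign_fragment(
    call1: AlleleCall, call2: Optional[AlleleCall] = None
) -> FragmentCall:
    """Combine the two end calls of one fragment (pairing rule).

    One allele-certain end assigns the pair; ends assigned to different
    alleles, or any CONFLICT end, discard the pair.
    """
    calls = [call1] if call2 is None else [call1, call2]
    if any(c is AlleleCall.CONFLICT for c in calls):
        return FragmentCall.DISCARD
    has0 = AlleleCall.ALLELE0 in calls
    has1 = AlleleCall.ALLELE1 in calls
    if has0 and has1:
        return FragmentCall.DISCARD
    if has0:
        return FragmentCall.ALLELE0
    if has1:
        return FragmentCall.ALLELE1
    return FragmentCall.UNCERTAIN


def dedup(fragments: Iterable[Fragment]) -> List[Fragment]:
    """Coordinate-based duplicate removal on the template's outer coordinates.

    Among fragments sharing (chrom, start, end, strand) only the first
    encountered is kept — a MarkDuplicates stand-in, applied to ATAC/ChIP
    fragments (not RNA-seq).
    """
    seen = set()
    kept: List[Fragment] = []
    for frag in fragments:
        key = (frag.chrom, frag.start, frag.end, frag.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(frag)
    return kept


# ---------------------------------------------------------------------------
# SAM -> fragments


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                skipped += 1
                continue
            yield AlignedRead.from_pysam(aln)
    if skipped:
        logger.info("%s: skipped %d unmapped/malformed records", path, skipped)


def fragments_from_reads(
    reads: Iterable[AlignedRead],
    snps: SnpIndex,
    paired: bool = True,
) -> List[Fragment]:
    """Pair up read ends, classify each end, and apply the pairing rule.

    Unpaired mode treats every read as its own fragment (a CONFLICT end is
    discarded).  Fragments with call DISCARD are dropped here; UNCERTAIN
    fragments are retained for diploid counting.
    """
    fragments: List[Fragment] = []
    if not paired:
        for read in reads:
            call = assign_fragment(classify_read(read, snps))
            if call is FragmentCall.DISCARD:
                continue
            fragments.append(_make_fragment([read], call))
        return fragments

    pending: "OrderedDict[str, AlignedRead]" = OrderedDict()
    for read in reads:
        mate = pending.pop(read.read_id, None)
        if mate is None:
            pending[read.read_id] = read
            continue
        call = assign_fragment(
            classify_read(mate, snps), classify_read(read, snps)
        )
        if call is FragmentCall.DISCARD:
            continue
        fragments.append(_make_fragment([mate, read], call))
    # orphans (mate filtered out) are treated as single-end fragments
    for read in pending.values():
        call = assign_fragment(classify_read(read, snps))
        if call is FragmentCall.DISCARD:
            continue
        fragments.append(_make_fragment([read], call))
    return fragments


def _make_fragment(reads: Sequence[AlignedRead], call: FragmentCall) -> Fragment:
    chrom = reads[0].chrom
    start = min(r.start for r in reads)
    end = max(r.end for r in reads)
    strand = "-" if reads[0].is_reverse else "+"
    blocks = [
        (ref_start, ref_start + length)
        for r in reads
        for _, ref_start, length in r.blocks
    ]
    return Fragment(reads[0].read_id, chrom, start, end, strand, call, blocks)


# ---------------------------------------------------------------------------
# Counting


def count_gene_alleles(
    fragments: Iterable[Fragment], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene exonic tallies of allele0/allele1/uncertain fragments.

    A fragment contributes to a gene iff at least one aligned base overlaps the
    gene's exon union; fragments overlapping exons of more than one gene are
    ambiguous and counted for none.

    Returns a DataFrame indexed by gene_id with integer columns
    n0, n1, n_uncertain, n_total.
    """
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        if not gene.exons:
            raise ValueError(f"gene {gene.gene_id} has no exons")
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for start, end in gene.exons:
            tree.addi(start, end, gene.gene_id)

    counts = {
        g.gene_id: {"n0": 0, "n1": 0, "n_uncertain": 0} for g in genes
    }
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        blocks = frag.blocks or [(frag.start, frag.end)]
        hit_genes = {
            iv.data for start, end in blocks for iv in tree.overlap(start, end)
        }
        if len(hit_genes) != 1:
            continue
        gene_id = hit_genes.pop()
        if frag.call is FragmentCall.ALLELE0:
            counts[gene_id]["n0"] += 1
        elif frag.call is FragmentCall.ALLELE1:
            counts[gene_id]["n1"] += 1
        else:
            counts[gene_id]["n_uncertain"] += 1

    table = pd.DataFrame.from_dict(counts, orient="index").astype(int)
    table.index.name = "gene_id"
    table["n_total"] = table["n0"] + table["n1"] + table["n_uncertain"]
    return table


def compute_mapping_bias(
    table: pd.DataFrame, genes: Sequence[GeneModel]
) -> MappingBias:
    """r_m = N_A0/N_A1 summed over autosomal genes only."""
    autosomal = [g.gene_id for g in genes if g.is_autosomal]
    sub = table.loc[table.index.intersection(autosomal)]
    n_a0 = int(sub["n0"].sum())
    n_a1 = int(sub["n1"].sum())
    if n_a1 == 0:
        raise ValueError("mapping bias undefined: no allele1 autosomal fragments")
    return MappingBias(n_a0=n_a0, n_a1=n_a1)


def mapping_metrics(fragments: Sequence[Fragment], n_discarded: int = 0) -> Dict:
    """Fractions of fragments per allele call plus the discard count."""
    total = len(fragments)
    tally = {c: 0 for c in ("allele0", "allele1", "uncertain")}
    for frag in fragments:
        tally[frag.call.value] += 1
    fractions = {
        key: (count / total if total else 0.0) for key, count in tally.items()
    }
    return {
        "n_fragments": total,
        "counts": tally,
        "fractions": fractions,
        "allele_certain_fraction": fractions["allele0"] + fractions["allele1"],
        "n_discarded": n_discarded,
    }
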