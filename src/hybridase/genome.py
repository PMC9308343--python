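"""Pseudo-genome construction and SNP indexing.

In an F1 hybrid between two inbred strains, reads from the alternate-strain
haplotype mismatch the reference at every strain-distinguishing SNP.  Mapping
both haplotypes fairly requires an alternate-strain ("pseudo") genome built by
substituting the known strain SNPs into the reference.  This module builds that
genome and a position-indexed SNP lookup used by read classification.

Coordinates are 0-based half-open throughout the package; 1-based VCF input is
converted on read.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic strain-distinguishing SNP.

    ``ref_allele`` is the reference-strain (allele0 / BL6) base and
    ``alt_allele`` the alternate-strain (allele1 / cast) base, both uppercase.
    ``pos`` is 0-based.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative SNP position {self.chrom}:{self.pos}")
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(
                f"SNP {self.chrom}:{self.pos} alleles must be single A/C/G/T "
                f"bases, got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if ref == alt:
            raise ValueError(
                f"SNP {self.chrom}:{self.pos} has identical alleles {ref}"
            )
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)

    def swapped(self) -> "SnpRecord":
        """The same site with ref and alt exchanged (strain-swap symmetry)."""
        return SnpRecord(self.chrom, self.pos, self.alt_allele, self.ref_allele)


class SnpIndex:
    """Sorted per-chromosome SNP lookup supporting point and interval queries."""

    def __init__(self, snps: Iterable[SnpRecord]):
        by_chrom: Dict[str, Dict[int, SnpRecord]] = {}
        for snp in snps:
            seen = by_chrom.setdefault(snp.chrom, {})
            prev = seen.get(snp.pos)
            if prev is not None:
                if (prev.ref_allele, prev.alt_allele) != (
                    snp.ref_allele,
                    snp.alt_allele,
                ):
                    raise ValueError(
                        f"conflicting alleles at {snp.chrom}:{snp.pos}: "
                        f"{prev.ref_allele}>{prev.alt_allele} vs "
                        f"{snp.ref_allele}>{snp.alt_allele}"
                    )
                continue
            seen[snp.pos] = snp
        self._records: Dict[str, List[SnpRecord]] = {}
        self._positions: Dict[str, List[int]] = {}
        for chrom, seen in by_chrom.items():
            recs = [seen[p] for p in sorted(seen)]
            self._records[chrom] = recs
            self._positions[chrom] = [r.pos for r in recs]

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    @property
    def chroms(self) -> List[str]:
        return sorted(self._records)

    def at(self, chrom: str, pos: int) -> Optional[SnpRecord]:
        """The SNP at (chrom, pos), or None if the site is not a SNP."""
        positions = self._positions.get(chrom)
        if not positions:
            return None
        i = bisect_left(positions, pos)
        if i < len(positions) and positions[i] == pos:
            return self._records[chrom][i]
        return None

    def overlapping(self, chrom: str, start: int, end: int) -> List[SnpRecord]:
        """SNPs with start <= pos < end, in position order."""
        positions = self._positions.get(chrom)
        if not positions:
            return []
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end - 1)
        return self._records[chrom][lo:hi]

    def all_records(self) -> List[SnpRecord]:
        return [r for c in sorted(self._records) for r in self._records[c]]

    def swapped(self) -> "SnpIndex":
        return SnpIndex(r.swapped() for r in self.all_records())


def build_snp_index(snps: Iterable[SnpRecord]) -> SnpIndex:
    return SnpIndex(snps)


def build_pseudo_genome(
    sequences: Mapping[str, str], snps: Sequence[SnpRecord]
) -> Dict[str, str]:
    """Substitute alternate-strain SNP bases into the reference sequences.

    Every SNP's ref_allele must match the reference base at its position
    (case-insensitively; soft-masked lowercase is preserved in the output).
    Output sequences have the same names and lengths as the input.
    """
    mutable = {name: bytearray(seq, "ascii") for name, seq in sequences.items()}
    for snp in snps:
        if snp.chrom not in mutable:
            raise KeyError(f"SNP on unknown chromosome {snp.chrom!r}")
        seq = mutable[snp.chrom]
        if snp.pos >= len(seq):
            raise ValueError(
                f"SNP position {snp.chrom}:{snp.pos} beyond chromosome "
                f"length {len(seq)}"
            )
        ref_base = chr(seq[snp.pos])
        if ref_base.upper() != snp.ref_allele:
            raise ValueError(
                f"reference mismatch at {snp.chrom}:{snp.pos}: expected "
                f"{snp.ref_allele}, found {ref_base}"
            )
        alt = snp.alt_allele if ref_base.isupper() else snp.alt_allele.lower()
        seq[snp.pos] = ord(alt)
    return {name: seq.decode("ascii") for name, seq in mutable.items()}


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_snps(path: str | Path) -> List[SnpRecord]:
    """Read strain SNPs from VCF (1-based, converted) or 4-column TSV.

    TSV columns: chrom, pos (1-based), ref, alt.  Indels and multiallelic
    records are skipped with a logged count; only biallelic single-nucleotide
    substitutions are retained.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return _read_snps_vcf(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom\tpos0"):  # already-normalized 0-based table
        return read_snp_tsv0(path)
    return _read_snps_tsv(path)


def _read_snps_vcf(path: Path) -> List[SnpRecord]:
    from cyvcf2 import VCF

    snps: List[SnpRecord] = []
    skipped = 0
    for var in VCF(str(path)):
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        if var.REF.upper() not in _BASES or alts[0].upper() not in _BASES:
            skipped += 1
            continue
        snps.append(SnpRecord(var.CHROM, var.POS - 1, var.REF, alts[0]))
    if skipped:
        logger.info("skipped %d non-SNP/multiallelic VCF records", skipped)
    return snps


def _read_snps_tsv(path: Path) -> List[SnpRecord]:
    snps: List[SnpRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos1, ref, alt = line.split("\t")[:4]
            if len(ref) != 1 or len(alt) != 1 or ref.upper() == alt.upper():
                skipped += 1
                continue
            if ref.upper() not in _BASES or alt.upper() not in _BASES:
                skipped += 1
                continue
            snps.append(SnpRecord(chrom, int(pos1) - 1, ref, alt))
    if skipped:
        logger.info("skipped %d non-SNP TSV records", skipped)
    return snps


def write_snp_tsv(snps: Sequence[SnpRecord], path: str | Path) -> None:
    """Write a normalized 0-based SNP table for downstream stages."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos0\tref\talt\n")
        for snp in snps:
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.ref_allele}\t{snp.alt_allele}\n")


def read_snp_tsv0(path: str | Path) -> List[SnpRecord]:
    """Read the normalized 0-based SNP table written by :func:`write_snp_tsv`."""
    snps: List[SnpRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\tpos0"):
            raise ValueError(f"{path} is not a normalized 0-based SNP table")
        for line in fh:
            chrom, pos0, ref, alt = line.rstrip("\n").split("\t")[:4]
            snps.append(SnpRecord(chrom, int(pos0), ref, alt))
    return snps
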