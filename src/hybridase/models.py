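"""Gene models: exon structures, TSS, and chromosome class.

A gene model is the merged exon set of a gene plus its strand and TSS.  Exonic
fragment counts and TPM normalization use the exon-union length; promoter
windows are centred on the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

X_NAMES = {"X", "chrX"}
Y_NAMES = {"Y", "chrY"}


def merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted union."""
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def chrom_class(chrom: str) -> str:
    if chrom in X_NAMES:
        return "X"
    if chrom in Y_NAMES:
        return "Y"
    return "autosome"


@dataclass
class GeneModel:
    """A gene as a merged exon union on one strand.

    Exons are 0-based half-open and stored merged/sorted; the TSS is the
    5'-most exon boundary respecting strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: empty exon list")
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.gene_id}: empty exon ({start},{end})")
        self.exons = merge_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exon_union_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def chrom_class(self) -> str:
        return chrom_class(self.chrom)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom_class == "autosome"


def write_gene_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write a BED12-like gene table (0-based, comma-joined exon bounds)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{starts}\t{ends}\n")


def read_gene_tsv(path: str | Path) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene_id", "chrom", "strand", "exon_starts", "exon_ends"}
        if not required <= set(idx):
            raise ValueError(f"{path}: missing columns {required - set(idx)}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            starts = [int(x) for x in parts[idx["exon_starts"]].split(",")]
            ends = [int(x) for x in parts[idx["exon_ends"]].split(",")]
            genes.append(
                GeneModel(
                    gene_id=parts[idx["gene_id"]],
                    chrom=parts[idx["chrom"]],
                    strand=parts[idx["strand"]],
                    exons=list(zip(starts, ends)),
                )
            )
    return genes
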