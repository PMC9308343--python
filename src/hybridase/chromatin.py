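"""Allelic ATAC/ChIP fragment coverage at promoters and custom regions.

Promoters are symmetric +/-2 kb windows around the TSS.  Coverage is counted
at the fragment level per (region, allele), scaled to fragments per million
assigned fragments, optionally normalized by a matched input control
(ChIP), and quantile-normalized across alleles and cell lines under the
assumption that promoter coverage distributions are comparable.  Per-group
shifts of log2(KO/wt) ratios are tested with a two-sided Wilcoxon signed-rank
test against zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .alleles import Fragment, FragmentCall
from .models import GeneModel
from .sexbias import quantile_normalize

PROMOTER_FLANK = 2000
INPUT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic window."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str = "custom"  # promoter | enhancer | custom

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.name}: end must exceed start")


def make_promoters(
    genes: Sequence[GeneModel],
    chrom_lengths: Optional[Mapping[str, int]] = None,
    flank: int = PROMOTER_FLANK,
) -> List[Region]:
    """One [tss-flank, tss+flank) window per gene, clipped at chromosome
    bounds; strand does not change the window (symmetric definition)."""
    regions = []
    for gene in genes:
        limit = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        if limit is not None and not (0 <= gene.tss < limit):
            raise ValueError(
                f"{gene.gene_id}: TSS {gene.tss} outside chromosome "
                f"{gene.chrom} (length {limit})"
            )
        start = max(gene.tss - flank, 0)
        end = gene.tss + flank
        if limit is not None:
            end = min(end, limit)
        regions.append(Region(gene.chrom, start, end, gene.gene_id, "promoter"))
    return regions


def read_bed(path: str | Path, kind: str = "custom") -> List[Region]:
    """Regions from a BED file (0-based half-open; name column optional)."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"region_{i}"
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name, kind))
    return regions


def region_coverage(
    fragments: Sequence[Fragment], regions: Sequence[Region]
) -> pd.DataFrame:
    """Fragment counts per (region, allele) with depth scaling.

    A fragment (outer template span) counts toward every region it overlaps
    by >= 1 bp — overlapping regions are independent.  Columns: maternal-,
    paternal-oriented callers should have relabelled calls beforehand; here
    counts are keyed by the fragment's call (allele0/allele1/uncertain) plus
    a 'diploid' column summing all three.  depth-scaled values are counts *
    1e6 / total fragments in the sample.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, region in enumerate(regions):
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, i
        )
    names = [r.name for r in regions]
    cols = ["allele0", "allele1", "uncertain"]
    counts = np.zeros((len(regions), len(cols)), dtype=int)
    col_idx = {c: j for j, c in enumerate(cols)}
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        j = col_idx[frag.call.value]
        for iv in tree.overlap(frag.start, frag.end):
            counts[iv.data, j] += 1
    table = pd.DataFrame(counts, index=pd.Index(names, name="region"), columns=cols)
    table["diploid"] = table.sum(axis=1)
    total = len(fragments)
    scale = 1e6 / total if total else 0.0
    for col in cols + ["diploid"]:
        table[f"{col}_per_million"] = table[col] * scale
    return table


def allelic_coverage_matrix(
    coverage_by_sample: Mapping[str, pd.DataFrame],
    allele_column: str,
) -> pd.DataFrame:
    """Stack one depth-scaled coverage column across samples into a
    regions x samples matrix (for QN and ratio computation)."""
    cols = {
        sample: table[f"{allele_column}_per_million"]
        for sample, table in coverage_by_sample.items()
    }
    return pd.DataFrame(cols)


def input_normalize(
    chip: pd.Series, control: pd.Series, pseudocount: float = INPUT_PSEUDOCOUNT
) -> pd.Series:
    """(chip + pc) / (input + pc) on depth-scaled coverage values."""
    chip, control = chip.align(control, join="left")
    if control.isna().any():
        missing = list(chip.index[control.isna()])[:5]
        raise KeyError(f"input control missing regions, e.g. {missing}")
    return (chip + pseudocount) / (control + pseudocount)


def qn_across(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize coverage across alleles/lines (columns).

    Delegates to the expression-side quantile normalization; all columns must
    describe the same region set.
    """
    if matrix.isna().any().any():
        raise ValueError("mismatched region sets across groups")
    return quantile_normalize(matrix)


def group_shift_test(
    log2_ratios: Sequence[float], min_genes: int = 5
) -> Dict[str, float]:
    """Median and Wilcoxon signed-rank p of per-gene log2(KO/wt) against 0.

    Raises if fewer than ``min_genes`` ratios are supplied; a degenerate
    all-identical input yields p = NaN with a flag.
    """
    ratios = np.asarray(log2_ratios, dtype=float)
    ratios = ratios[~np.isnan(ratios)]
    if len(ratios) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(ratios)}")
    median = float(np.median(ratios))
    if np.allclose(ratios, ratios[0]) and np.allclose(ratios[0], 0.0):
        return {"n": len(ratios), "median": median, "p_value": float("nan"),
                "degenerate": True}
    try:
        _, p = stats.wilcoxon(ratios, alternative="two-sided")
    except ValueError:  # all differences zero
        return {"n": len(ratios), "median": median, "p_value": float("nan"),
                "degenerate": True}
    return {"n": len(ratios), "median": median, "p_value": float(p),
            "degenerate": False}


def group_shift_summary(
    ratios_by_group: Mapping[str, Sequence[float]],
    allele: str = "",
    assay: str = "",
) -> List[Dict]:
    """Per-group shift statistics, one record per group label."""
    out = []
    for group, ratios in ratios_by_group.items():
        rec = {"group": group, "allele": allele, "assay": assay}
        rec.update(group_shift_test(ratios))
        out.append(rec)
    return out
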