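"""Diploid TPM and its bias-corrected allelic decomposition.

For gene *i* with exonic allele-informative counts n0 (allele0/BL6) and n1
(allele1/cast), the raw allele0 proportion is p0 = n0/(n0+n1).  Because reads
map slightly more efficiently to the strain matching the reference, the
proportion is corrected with the genome-wide autosomal mapping ratio
r_m = N_A0/N_A1:

    p0_adj = n0 / (n0 + r_m * n1)

The diploid TPM is assumed to be the sum of the two haploid TPMs, so
TPM_allele0 = p0_adj * TPM and TPM_allele1 = (1 - p0_adj) * TPM.  Maternal and
paternal values follow from the cross: BC (BL6 mother) maps maternal to
allele0; the reciprocal CB cross maps maternal to allele1.  In male samples,
X-linked paternal expression is masked to zero (the single X is maternal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .models import GeneModel


@dataclass
class SampleMeta:
    """Sample annotation: cross (BC/CB), sex, genotype, replicate label."""

    sample_id: str
    cross: str  # BC | CB
    sex: str  # M | F
    genotype: str  # wt | KO
    replicate: str = "1"
    exclusion_list: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.cross not in {"BC", "CB"}:
            raise ValueError(f"{self.sample_id}: unknown cross {self.cross!r}")
        if self.sex not in {"M", "F"}:
            raise ValueError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.genotype not in {"wt", "KO"}:
            raise ValueError(
                f"{self.sample_id}: unknown genotype {self.genotype!r}"
            )

    @property
    def maternal_allele(self) -> int:
        """0 if the maternal strain is the reference strain (BC), else 1."""
        return 0 if self.cross == "BC" else 1


def read_sample_sheet(path: str | Path) -> List[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cross", "sex", "genotype"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                cross=row["cross"],
                sex=row["sex"],
                genotype=row["genotype"],
                replicate=row.get("replicate", "1"),
            )
        )
    return metas


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "cross": m.cross,
            "sex": m.sex,
            "genotype": m.genotype,
            "replicate": m.replicate,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(counts: pd.Series, genes: Sequence[GeneModel]) -> pd.Series:
    """Transcripts per kilobase of exon length per million mapped fragments.

    rate_i = count_i / exon_union_kb_i; TPM_i = 1e6 * rate_i / sum_j rate_j.
    The library size is the sum of exonic fragments of counted genes.
    """
    lengths_kb = pd.Series(
        {g.gene_id: g.exon_union_length / 1000.0 for g in genes}
    )
    lengths_kb = lengths_kb.reindex(counts.index)
    if lengths_kb.isna().any():
        missing = list(counts.index[lengths_kb.isna()])[:5]
        raise KeyError(f"counts for genes without models, e.g. {missing}")
    rate = counts / lengths_kb
    total = rate.sum()
    if total <= 0:
        raise ValueError("all counts are zero; TPM undefined")
    return 1e6 * rate / total


def compute_tpm_matrix(
    counts: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    return counts.apply(lambda col: compute_tpm(col, genes))


def expressed_filter(tpm: pd.DataFrame, min_tpm: float = 1.0) -> pd.Index:
    """Genes with TPM > min_tpm in at least one sample (column)."""
    return tpm.index[(tpm > min_tpm).any(axis=1)]


# ---------------------------------------------------------------------------
# Allelic proportions


def allelic_proportion(n0, n1, r_m: float):
    """Raw and bias-adjusted allele0 proportions.

    Returns (p0, p0_adj); NaN where n0 + n1 == 0 (no allelic information).
    Accepts scalars or aligned array-likes.
    """
    if r_m <= 0:
        raise ValueError("r_m must be positive")
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    informative = (n0 + n1) > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(informative, n0 / (n0 + n1), np.nan)
        p0_adj = np.where(informative, n0 / (n0 + r_m * n1), np.nan)
    if p0.ndim == 0:
        return float(p0), float(p0_adj)
    return p0, p0_adj


def decompose_tpm(tpm, p0_adj):
    """Split diploid TPM into the two haploid TPMs: (p0_adj*tpm, (1-p0_adj)*tpm)."""
    tpm = np.asarray(tpm, dtype=float)
    p0_adj = np.asarray(p0_adj, dtype=float)
    tpm0 = p0_adj * tpm
    tpm1 = (1.0 - p0_adj) * tpm
    if tpm0.ndim == 0:
        return float(tpm0), float(tpm1)
    return tpm0, tpm1


def allelic_expression_table(
    counts: pd.DataFrame,
    diploid_counts: pd.Series,
    genes: Sequence[GeneModel],
    meta: SampleMeta,
    r_m: float,
) -> pd.DataFrame:
    """Per-gene allelic expression record for one sample.

    ``counts`` must carry columns n0/n1 (one row per gene); ``diploid_counts``
    the total exonic fragments used for TPM.  Orientation and X masking are
    applied.  Columns: tpm, p0, p0_adj, tpm_allele0, tpm_allele1,
    tpm_maternal, tpm_paternal, masked.
    """
    tpm = compute_tpm(diploid_counts, genes)
    p0, p0_adj = allelic_proportion(
        counts["n0"].to_numpy(), counts["n1"].to_numpy(), r_m
    )
    tpm0, tpm1 = decompose_tpm(tpm.reindex(counts.index).to_numpy(), p0_adj)
    table = pd.DataFrame(
        {
            "tpm": tpm.reindex(counts.index),
            "p0": p0,
            "p0_adj": p0_adj,
            "tpm_allele0": tpm0,
            "tpm_allele1": tpm1,
        },
        index=counts.index,
    )
    table = orient_alleles(table, meta)
    table = mask_x_paternal(table, genes, meta)
    return table


def orient_alleles(table: pd.DataFrame, meta: SampleMeta) -> pd.DataFrame:
    """Add maternal/paternal TPM columns according to the cross.

    BC: maternal = allele0 (BL6 mother); CB: maternal = allele1.  Idempotent —
    existing orientation columns are recomputed from the allele columns.
    """
    table = table.copy()
    if meta.maternal_allele == 0:
        table["tpm_maternal"] = table["tpm_allele0"]
        table["tpm_paternal"] = table["tpm_allele1"]
    else:
        table["tpm_maternal"] = table["tpm_allele1"]
        table["tpm_paternal"] = table["tpm_allele0"]
    if "masked" not in table.columns:
        table["masked"] = False
    return table


def mask_x_paternal(
    table: pd.DataFrame, genes: Sequence[GeneModel], meta: SampleMeta
) -> pd.DataFrame:
    """In male samples, zero X-linked paternal expression and flag the gene.

    A male carries a single, maternally inherited X, so apparent paternal
    X-linked signal is noise and is masked.
    """
    table = table.copy()
    if "masked" not in table.columns:
        table["masked"] = False
    if meta.sex != "M":
        return table
    x_genes = [g.gene_id for g in genes if g.chrom_class == "X"]
    idx = table.index.intersection(x_genes)
    table.loc[idx, "tpm_paternal"] = 0.0
    table.loc[idx, "masked"] = True
    return table


def orient_counts(
    counts: pd.DataFrame, meta: SampleMeta
) -> pd.DataFrame:
    """Relabel n0/n1 columns as maternal/paternal counts for one sample."""
    if meta.maternal_allele == 0:
        mat, pat = counts["n0"], counts["n1"]
    else:
        mat, pat = counts["n1"], counts["n0"]
    return pd.DataFrame(
        {"n_maternal": mat, "n_paternal": pat}, index=counts.index
    )
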