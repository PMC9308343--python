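"""Read classification, the pairing rule, deduplication, and counting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hybridase.alleles import (
    AlignedRead,
    AlleleCall,
    Fragment,
    FragmentCall,
    assign_fragment,
    classify_read,
    compute_mapping_bias,
    count_gene_alleles,
    dedup,
    filter_alignments,
    mapping_metrics,
)
from hybridase.genome import SnpRecord, build_snp_index
from hybridase.models import GeneModel


def simple_read(seq, start=0, chrom="c", mapq=60, unique=True, blocks=None):
    if blocks is None:
        blocks = [(0, start, len(seq))]
    return AlignedRead(
        read_id="r",
        chrom=chrom,
        start=start,
        blocks=blocks,
        sequence=seq,
        mapq=mapq,
        is_unique=unique,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "mapq,unique,kept",
        [(30, True, True), (29, True, False), (40, False, False), (0, True, False)],
    )
    def test_mapq_and_uniqueness_rule(self, mapq, unique, kept):
        reads = [simple_read("ACGT", mapq=mapq, unique=unique)]
        assert (len(list(filter_alignments(reads, 30))) == 1) is kept

    def test_order_preserved(self):
        reads = [simple_read(s, mapq=30 + i) for i, s in enumerate("AC")]
        out = list(filter_alignments(reads, 30))
        assert [r.sequence for r in out] == ["A", "C"]


class TestClassifyRead:
    index = build_snp_index(
        [SnpRecord("c", 2, "A", "G"), SnpRecord("c", 7, "C", "T")]
    )

    def test_alt_base_gives_allele1(self):
        read = simple_read("AAGAA", start=0)  # base G at SNP pos 2
        assert classify_read(read, self.index) is AlleleCall.ALLELE1

    def test_ref_base_gives_allele0(self):
        read = simple_read("AAAAA", start=0)
        assert classify_read(read, self.index) is AlleleCall.ALLELE0

    def test_no_snp_overlap_is_uncertain(self):
        read = simple_read("AAA", start=3)  # covers 3..6, between SNPs
        assert classify_read(read, self.index) is AlleleCall.UNCERTAIN

    def test_mixed_evidence_is_conflict(self):
        # covers SNPs at 2 (ref base A) and 7 (alt base T)
        read = simple_read("AAAAATTT", start=0)
        assert classify_read(read, self.index) is AlleleCall.CONFLICT

    def test_error_base_ignored(self):
        # base C at SNP pos 2 matches neither A nor G: no vote -> uncertain
        read = simple_read("AACAA", start=0)
        assert classify_read(read, self.index) is AlleleCall.UNCERTAIN

    def test_snp_in_skipped_intron_does_not_vote(self):
        # spliced read covering 0..2 and 5..8: SNP at 2 skipped, SNP at 7 hit
        read = simple_read(
            "AAAAT", start=0, blocks=[(0, 0, 2), (2, 5, 3)]
        )  # read offset 4 -> ref pos 7, base T = alt
        assert classify_read(read, self.index) is AlleleCall.ALLELE1

    def test_agrees_with_per_base_oracle_and_swap_symmetry(self, rng):
        """Randomized reads versus a brute-force per-base oracle, plus the
        ref/alt swap symmetry (allele0 and allele1 calls exchange exactly)."""
        length = 5000
        seq = "".join(rng.choice(list("ACGT"), size=length))
        positions = sorted(rng.choice(length, size=150, replace=False))
        snps = []
        for pos in positions:
            ref = seq[pos]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            snps.append(SnpRecord("c", int(pos), ref, alt))
        index = build_snp_index(snps)
        swapped = index.swapped()
        by_pos = {s.pos: s for s in snps}

        swap_map = {
            AlleleCall.ALLELE0: AlleleCall.ALLELE1,
            AlleleCall.ALLELE1: AlleleCall.ALLELE0,
            AlleleCall.UNCERTAIN: AlleleCall.UNCERTAIN,
            AlleleCall.CONFLICT: AlleleCall.CONFLICT,
        }
        for _ in range(2000):
            start = int(rng.integers(0, length - 60))
            read_seq = list(seq[start : start + 60])
            # mutate a few bases (some on SNPs, some off)
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, 60))
                read_seq[i] = "ACGT"[int(rng.integers(0, 4))]
            read = simple_read("".join(read_seq), start=start)

            saw0 = saw1 = False  # oracle: scan every base
            for i, base in enumerate(read.sequence):
                snp = by_pos.get(start + i)
                if snp is None:
                    continue
                if base == snp.ref_allele:
                    saw0 = True
                elif base == snp.alt_allele:
                    saw1 = True
            if saw0 and saw1:
                expected = AlleleCall.CONFLICT
            elif saw0:
                expected = AlleleCall.ALLELE0
            elif saw1:
                expected = AlleleCall.ALLELE1
            else:
                expected = AlleleCall.UNCERTAIN

            got = classify_read(read, index)
            assert got is expected
            assert classify_read(read, swapped) is swap_map[got]


class TestAssignFragment:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            (AlleleCall.ALLELE0, AlleleCall.UNCERTAIN, FragmentCall.ALLELE0),
            (AlleleCall.UNCERTAIN, AlleleCall.ALLELE0, FragmentCall.ALLELE0),
            (AlleleCall.ALLELE1, AlleleCall.UNCERTAIN, FragmentCall.ALLELE1),
            (AlleleCall.ALLELE0, AlleleCall.ALLELE1, FragmentCall.DISCARD),
            (AlleleCall.ALLELE1, AlleleCall.ALLELE0, FragmentCall.DISCARD),
            (AlleleCall.UNCERTAIN, AlleleCall.UNCERTAIN, FragmentCall.UNCERTAIN),
            (AlleleCall.ALLELE0, AlleleCall.ALLELE0, FragmentCall.ALLELE0),
            (AlleleCall.CONFLICT, AlleleCall.ALLELE0, FragmentCall.DISCARD),
        ],
    )
    def test_pairing_rule(self, c1, c2, expected):
        assert assign_fragment(c1, c2) is expected

    @pytest.mark.parametrize(
        "call,expected",
        [
            (AlleleCall.ALLELE0, FragmentCall.ALLELE0),
            (AlleleCall.ALLELE1, FragmentCall.ALLELE1),
            (AlleleCall.UNCERTAIN, FragmentCall.UNCERTAIN),
            (AlleleCall.CONFLICT, FragmentCall.DISCARD),
        ],
    )
    def test_single_end(self, call, expected):
        assert assign_fragment(call) is expected

    def test_exhaustive_truth_table_properties(self):
        """Every two-end combination: symmetric, and never invents an allele."""
        calls = list(AlleleCall)
        for c1, c2 in itertools.product(calls, calls):
            out = assign_fragment(c1, c2)
            assert out is assign_fragment(c2, c1)
            if out in (FragmentCall.ALLELE0, FragmentCall.ALLELE1):
                assert AlleleCall(out.value) in (c1, c2)


def frag(chrom, start, end, strand="+", call=FragmentCall.UNCERTAIN, rid="f"):
    return Fragment(rid, chrom, start, end, strand, call, [(start, end)])


class TestDedup:
    def test_identical_coordinates_collapse(self):
        kept = dedup([frag("c", 0, 100), frag("c", 0, 100)])
        assert len(kept) == 1

    def test_different_end_both_kept(self):
        kept = dedup([frag("c", 0, 100), frag("c", 0, 101)])
        assert len(kept) == 2

    def test_strand_distinguishes(self):
        kept = dedup([frag("c", 0, 100, "+"), frag("c", 0, 100, "-")])
        assert len(kept) == 2

    def test_planted_duplicates_match_brute_force(self, rng):
        originals = [
            frag("c", int(s), int(s) + int(l), rid=f"f{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 10_000, 100), rng.integers(50, 300, 100))
            )
        ]
        dup_idx = rng.choice(100, size=10, replace=False)
        fragments = originals + [originals[i] for i in dup_idx]
        kept = dedup(fragments)
        expected = len({(f.chrom, f.start, f.end, f.strand) for f in fragments})
        assert len(kept) == expected


class TestCounting:
    genes = [
        GeneModel("g1", "c", "+", [(100, 200), (300, 400)]),
        GeneModel("g2", "c", "+", [(600, 800)]),
        GeneModel("gx", "chrX", "+", [(0, 200)]),
    ]

    def test_single_allele1_fragment(self):
        table = count_gene_alleles(
            [frag("c", 120, 180, call=FragmentCall.ALLELE1)], self.genes
        )
        assert table.loc["g1", "n1"] == 1
        assert table.loc["g1", "n_total"] == 1
        assert table.loc["g2"].sum() == 0

    def test_intronic_fragment_not_counted(self):
        table = count_gene_alleles([frag("c", 210, 290)], self.genes)
        assert table["n_total"].sum() == 0

    def test_ambiguous_two_gene_fragment_dropped(self):
        table = count_gene_alleles([frag("c", 150, 700)], self.genes)
        assert table["n_total"].sum() == 0

    def test_empty_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "c", "+", [])

    def test_random_fragments_match_brute_force_tally(self, rng):
        calls = [FragmentCall.ALLELE0, FragmentCall.ALLELE1, FragmentCall.UNCERTAIN]
        fragments = []
        for i in range(50):
            start = int(rng.integers(0, 900))
            fragments.append(
                frag("c", start, start + 60, call=calls[int(rng.integers(0, 3))],
                     rid=f"f{i}")
            )
        table = count_gene_alleles(fragments, self.genes)
        # brute-force: overlap each fragment against each gene's exons
        for gene in self.genes:
            tally = {"n0": 0, "n1": 0, "n_uncertain": 0}
            for f in fragments:
                hits = [
                    g for g in self.genes
                    if g.chrom == f.chrom
                    and any(s < f.end and f.start < e for s, e in g.exons)
                ]
                if len(hits) == 1 and hits[0].gene_id == gene.gene_id:
                    key = {
                        FragmentCall.ALLELE0: "n0",
                        FragmentCall.ALLELE1: "n1",
                        FragmentCall.UNCERTAIN: "n_uncertain",
                    }[f.call]
                    tally[key] += 1
            for key, value in tally.items():
                assert table.loc[gene.gene_id, key] == value


class TestMappingBias:
    genes = [
        GeneModel("a1", "chr1", "+", [(0, 100)]),
        GeneModel("x1", "chrX", "+", [(0, 100)]),
    ]

    def test_ratio_formula(self):
        table = pd.DataFrame(
            {"n0": [110], "n1": [100], "n_uncertain": [0], "n_total": [210]},
            index=pd.Index(["a1"], name="gene_id"),
        )
        assert compute_mapping_bias(table, self.genes).r_m == pytest.approx(1.1)

    def test_equal_totals_give_unity(self):
        table = pd.DataFrame(
            {"n0": [50], "n1": [50], "n_uncertain": [0], "n_total": [100]},
            index=pd.Index(["a1"], name="gene_id"),
        )
        assert compute_mapping_bias(table, self.genes).r_m == 1.0

    def test_x_linked_counts_excluded(self):
        table = pd.DataFrame(
            {
                "n0": [10, 100],
                "n1": [0, 100],
                "n_uncertain": [0, 0],
                "n_total": [10, 200],
            },
            index=pd.Index(["a1", "x1"], name="gene_id"),
        )
        with pytest.raises(ValueError, match="undefined"):
            compute_mapping_bias(table, self.genes)


class TestMetrics:
    def test_fractions(self):
        fragments = (
            [frag("c", 0, 10, call=FragmentCall.ALLELE0)]
            + [frag("c", 0, 10, call=FragmentCall.ALLELE1)]
            + [frag("c", 0, 10, call=FragmentCall.UNCERTAIN)] * 8
        )
        m = mapping_metrics(fragments)
        assert m["fractions"] == {
            "allele0": 0.1, "allele1": 0.1, "uncertain": 0.8
        }
        assert m["allele_certain_fraction"] == pytest.approx(0.2)

    def test_empty_input(self):
        m = mapping_metrics([])
        assert m["n_fragments"] == 0
        assert m["allele_certain_fraction"] == 0.0
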