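"""Self-contained verification experiments on synthetic data.

Each function runs one calibration or recovery experiment from scratch under
a caller-supplied seed and returns the measured quantities.  They back both
the verification test suite and the reproduction script, so the numbers those
two report are always produced by the same computation.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import differential as de
from . import quantify as qt
from .alleles import AlleleCall, classify_read
from .chromatin import group_shift_test
from .genome import SnpRecord, build_snp_index
from .simulate import SimConfig, _lengths_only, simulate_counts, simulate_genes, simulate_truth


def proportion_recovery(
    seed: int,
    n_genes: int = 2000,
    informative_depth: int = 600,
    r_true: float = 1.3,
) -> Dict[str, float]:
    """Recovery of planted maternal fractions by the bias-corrected estimator.

    Genes take maternal fractions on the grid {0.1, ..., 0.9}; informative
    allele counts are drawn under a planted mapping bias (allele0 recovery
    boosted by sqrt(r_true), allele1 suppressed by the same factor).  The
    genome-wide ratio r_m is estimated from the data and used to correct.
    Returns mean absolute errors of the corrected and raw proportions against
    the planted fractions, and of the raw proportion against its predicted
    distortion f*r/(f*r + 1 - f).
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.1, 0.9, 9)
    f = np.tile(grid, int(np.ceil(n_genes / len(grid))))[:n_genes]
    boost = math.sqrt(r_true)
    n0 = rng.poisson(informative_depth * f * boost)
    n1 = rng.poisson(informative_depth * (1.0 - f) / boost)
    # the symmetric grid plays the role of the autosome-wide average
    r_m = n0.sum() / n1.sum()
    p0, p0_adj = qt.allelic_proportion(n0, n1, r_m)
    predicted_raw = f * r_true / (f * r_true + 1.0 - f)
    return {
        "n_genes": n_genes,
        "r_m_estimate": float(r_m),
        "mae_adjusted": float(np.nanmean(np.abs(p0_adj - f))),
        "mae_raw": float(np.nanmean(np.abs(p0 - f))),
        "mae_raw_vs_predicted": float(np.nanmean(np.abs(p0 - predicted_raw))),
    }


def classifier_oracle_agreement(
    seed: int, n_reads: int = 10_000, genome_length: int = 20_000
) -> Dict[str, float]:
    """Fraction of reads on which SNP-overlap classification agrees with a
    brute-force per-base oracle (random genome, SNPs, and error-bearing
    reads)."""
    from .alleles import AlignedRead

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=genome_length))
    positions = sorted(rng.choice(genome_length, size=genome_length // 40,
                                  replace=False))
    snps = []
    for pos in positions:
        ref = seq[pos]
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        snps.append(SnpRecord("c", int(pos), ref, alt))
    index = build_snp_index(snps)
    by_pos = {s.pos: s for s in snps}

    read_len = 75
    agree = 0
    for _ in range(n_reads):
        start = int(rng.integers(0, genome_length - read_len))
        bases = list(seq[start : start + read_len])
        for _ in range(int(rng.integers(0, 3))):  # sprinkle mismatches
            i = int(rng.integers(0, read_len))
            bases[i] = "ACGT"[int(rng.integers(0, 4))]
        read_seq = "".join(bases)
        read = AlignedRead(
            read_id="r", chrom="c", start=start,
            blocks=[(0, start, read_len)], sequence=read_seq, mapq=60,
        )
        saw0 = saw1 = False
        for i, base in enumerate(read_seq):
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
        if classify_read(read, index) is expected:
            agree += 1
    return {"n_reads": n_reads, "agreement": agree / n_reads}


def _nb(rng, mu, alpha, size):
    lam = rng.gamma(1.0 / alpha, np.asarray(mu) * alpha, size=size)
    return rng.poisson(lam)


def null_calibration(
    seed: int,
    n_reps: int = 10,
    n_genes: int = 2000,
    dispersion: float = 0.1,
    level: float = 0.05,
) -> Dict[str, float]:
    """Empirical type-I error of the NB Wald test at the nominal level over
    replicated null simulations (no effects, 3 vs 3)."""
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_reps):
        mu = rng.lognormal(np.log(100), 1.0, n_genes)
        counts = pd.DataFrame(_nb(rng, mu[:, None], dispersion, (n_genes, 6)))
        res = de.nb_wald_test(counts, ["wt"] * 3 + ["KO"] * 3)
        rates.append(float((res["p_value"] < level).mean()))
    return {
        "n_reps": n_reps,
        "n_genes": n_genes,
        "type_one_error": float(np.mean(rates)),
        "per_rep": rates,
    }


def power_fourfold(
    seed: int,
    n_genes: int = 2000,
    n_effect: int = 200,
    mean_count: float = 200.0,
    dispersion: float = 0.05,
) -> Dict[str, float]:
    """Detection rate at FDR < 0.05 for fourfold effects of mean count 200
    embedded in a null background, 3 vs 3."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(100), 1.0, n_genes)
    mu[:n_effect] = mean_count
    fold = np.ones(n_genes)
    fold[:n_effect] = 4.0
    a = _nb(rng, mu[:, None], dispersion, (n_genes, 3))
    b = _nb(rng, (mu * fold)[:, None], dispersion, (n_genes, 3))
    counts = pd.DataFrame(np.hstack([a, b]))
    res = de.call_degs(de.nb_wald_test(counts, ["wt"] * 3 + ["KO"] * 3))
    detected = (res["direction"].to_numpy()[:n_effect] == "up").mean()
    return {"n_effect": n_effect, "power": float(detected)}


def group_recovery(seed: int, cross: str = "BC") -> Dict[str, float]:
    """End-to-end recovery of planted allelic groups A-F under the default
    synthetic study conditions, plus the partition check on the down set."""
    sim = simulate_counts(SimConfig(seed=seed))
    truth = sim.truth
    males = sim.samples_where(cross=cross, sex="M")
    condition = [m.genotype for m in males]
    mat = pd.DataFrame(
        {
            m.sample_id: qt.orient_counts(sim.allelic[m.sample_id], m)["n_maternal"]
            for m in males
        }
    )
    pat = pd.DataFrame(
        {
            m.sample_id: qt.orient_counts(sim.allelic[m.sample_id], m)["n_paternal"]
            for m in males
        }
    )
    mat_res, pat_res = de.allelic_deg_pipeline(mat, pat, condition)
    labels = de.classify_groups(mat_res, pat_res)

    recovered = planted_total = 0
    for name in "ABCDEF":
        planted = set(truth.index[truth["group"] == name])
        column = "down_group" if name in "ABC" else "up_group"
        found = set(labels.index[labels[column] == name])
        recovered += len(planted & found)
        planted_total += len(planted)

    mat_down, _ = de.deg_sets(mat_res)
    pat_down, _ = de.deg_sets(pat_res)
    down_all = mat_down | pat_down
    by_group = {g: set(labels.index[labels["down_group"] == g]) for g in "ABC"}
    partition_ok = (
        by_group["A"] | by_group["B"] | by_group["C"] == down_all
        and not (by_group["A"] & by_group["B"])
        and not (by_group["A"] & by_group["C"])
        and not (by_group["B"] & by_group["C"])
    )
    return {
        "n_planted": planted_total,
        "recovery": recovered / planted_total,
        "partition_ok": bool(partition_ok),
    }


def chromatin_pattern(seed: int) -> Dict[str, Dict[str, float]]:
    """Group-shift statistics of maternal H3K27me3 log2(KO/wt) ratios for
    the affected group A and the unaffected-allele group E."""
    from .simulate import simulate_chromatin

    config = SimConfig(seed=seed, n_genes=2000, crosses=("BC",))
    genes = simulate_genes(config, _lengths_only(config))
    truth = simulate_truth(config, genes)
    chrom = simulate_chromatin(config, genes, truth)
    wt = chrom.chip["BC_wt_M1"]
    ko = chrom.chip["BC_KO_M1"]
    ratios = np.log2((ko["maternal"] + 1) / (wt["maternal"] + 1))
    out = {}
    for name in ("A", "E"):
        idx = truth.index[truth["group"] == name]
        out[name] = group_shift_test(ratios.loc[idx])
    return out
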