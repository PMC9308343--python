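# hybridase

Allele-specific and sex-biased gene-regulation analysis for F1-hybrid mouse
embryonic stem cells.

In an F1 hybrid of two inbred strains (C57BL/6J × *M. castaneus*), exonic
SNPs distinguish the two parental alleles, so RNA-seq, ATAC-seq and ChIP-seq
reads can be assigned to the maternal or paternal chromosome.  Reciprocal
crosses (BC: BL6 mother; CB: cast mother) swap which strain is maternal,
separating parent-of-origin effects from strain effects.  `hybridase`
implements the full analysis stack for such designs:

- **Pseudo-genome construction** — substitute the alternate strain's SNPs
  into the reference so both haplotypes map comparably.
- **Allele assignment** — classify unique, high-quality (MAPQ ≥ 30)
  alignments by the SNP bases they cover into allele0 (BL6), allele1 (cast),
  or allele-uncertain; a read pair inherits the call of its allele-certain
  end, and pairs with conflicting ends are discarded.
- **Bias-corrected allelic expression** — for gene *i* with informative
  counts *n*ᵢ₀, *n*ᵢ₁, the raw allele0 proportion *p*ᵢ₀ = *n*ᵢ₀/(*n*ᵢ₀+*n*ᵢ₁)
  is corrected with the genome-wide autosomal mapping ratio
  *r*ₘ = *N*<sub>A0</sub>/*N*<sub>A1</sub>:

      p̂ᵢ₀ = nᵢ₀ / (nᵢ₀ + r_m · nᵢ₁)

  The diploid TPM splits into haploid TPMs, TPMᵢ₀ = p̂ᵢ₀·TPMᵢ and
  TPMᵢ₁ = (1−p̂ᵢ₀)·TPMᵢ, oriented to maternal/paternal by the cross.
- **Differential expression** — a compact negative-binomial Wald pipeline
  (median-of-ratios size factors, trend-shrunk moment dispersions), run on
  diploid and per-allele counts with FDR < 0.05 and ≥ 1.5-fold thresholds.
  Down-regulated allelic DEGs fall into groups **A** (maternal only),
  **B** (paternal only), **C** (both); up-regulated into **D/E/F**.
- **Sex-bias accounting** — sex-biased genes (≥ 2-fold TPM, Student's t
  *p* ≤ 0.05, female vs male wild type), their loss after knockout
  (cross-sex fold < 2) and gains (full criterion post-KO), with quantile
  normalization for comparisons against external wild-type matrices.
- **Allelic chromatin coverage** — fragment counts in promoter windows
  (TSS ± 2 kb), depth-scaled, input-normalized for ChIP, quantile-normalized
  across alleles and lines, with Wilcoxon signed-rank tests on per-group
  log2(KO/wt) shifts.
- **Synthetic hybrid generator** — simulates the whole study design (SNPs,
  haplotype-aware reads, mapping bias, imprinting, groups A–F, sex-bias
  loss, chromatin shifts) with ground truth, so every stage is testable
  without external data.

## Worked example

Simulate the default synthetic study (2,000 genes; two wild-type and three
knockout male clones per cross; planted mapping bias 1.2; fourfold allelic
knockout effects) and run the allelic differential analysis:

```python
import pandas as pd
from hybridase import SimConfig
from hybridase.simulate import simulate_counts
from hybridase.quantify import orient_counts
from hybridase.differential import (allelic_deg_pipeline, classify_groups,
                                    group_counts, allele_specific_summary)

sim = simulate_counts(SimConfig(seed=1))
truth, counts = sim.truth, sim.allelic

tab = counts["BC_wt_M1"]
auto = truth.index[truth.autosomal]
r_m = tab.loc[auto, "n0"].sum() / tab.loc[auto, "n1"].sum()
print(f"mapping bias r_m = {r_m:.3f} (planted 1.2)")

males = sim.samples_where(cross="BC", sex="M")
design = [m.genotype for m in males]
mat = pd.DataFrame({m.sample_id: orient_counts(counts[m.sample_id], m)["n_maternal"]
                    for m in males})
pat = pd.DataFrame({m.sample_id: orient_counts(counts[m.sample_id], m)["n_paternal"]
                    for m in males})
mat_res, pat_res = allelic_deg_pipeline(mat, pat, design)
labels = classify_groups(mat_res, pat_res)
summary = allele_specific_summary(group_counts(labels))
print("group counts:", group_counts(labels))
print("allele-specific share of down DEGs:",
      f"{summary['down']['allele_specific_percent']}%")
```

Output:

```
mapping bias r_m = 1.249 (planted 1.2)
group counts: {'A': 24, 'B': 23, 'C': 30, 'D': 25, 'E': 23, 'F': 49}
allele-specific share of down DEGs: 61%
```

The estimated mapping bias recovers the planted value; the group counts
recover the 20 genes planted per group, with the biallelic groups C and F
additionally picking up the simulated sex-bias collapse genes, whose
expression genuinely changes on both alleles in knockout males.

A `hybridase` command-line tool wraps the stages (`simulate`, `assign`,
`quant`, `de`, `sexbias`, `chromatin`, and `run` for a full configured
pipeline); see `hybridase --help`.

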