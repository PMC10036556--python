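# tsrnapipe

Analysis toolkit for sperm small non-coding RNA sequencing with a focus on
tRNA-derived fragments (tsRNAs), written for studies of paternal exposure
effects on offspring phenotypes — e.g. methotrexate (MTX)-treated medaka
males whose offspring develop cranial cartilage defects.  It provides the
complete computational arm of such a study: small RNA-seq read processing
and tRNA 5′/3′-half quantification, differential abundance statistics,
and the offspring morphometry/phenotype statistics, plus a seeded
simulator so that every stage can be exercised and validated without any
sequencing data.

## What it computes

**Read processing.**  Raw reads have the library structure
`[4 random nt][insert][6 random nt][3′ adapter…]`.  Two trimming chains are
implemented: the *sncRNA* chain (adapter removal, reads < 15 nt discarded;
random-nt removal; reads < 19 nt discarded) for class-level counting, and
the *halves* chain (the same, then 3 further nt clipped from the 3′ end and
reads < 15 nt discarded) for 5′/3′ tRNA-half counting.

**Alignment and counting.**  Reads are aligned ungapped and sense-strand to
a transcript-level sncRNA reference (rRNAs, tRNAs, miRNAs, snRNAs,
snoRNAs, …), keeping all placements with the minimum mismatch count
(≤ 1 mismatch).  A read with *n* placements contributes 1/*n* to each
overlapped feature (fractional multimapping).  Each tRNA is split into a 5′
and a 3′ half at the middle anticodon nucleotide; a read is assigned to the
half holding the majority of its bases.  RPM values are reads per million
assigned to the functional sncRNA categories; per-base coverage (bin
size 1) and weighted read-length distributions with medians are also
provided.

**Differential abundance.**  A simplified negative-binomial Wald test:
median-of-ratios size factors s_j, method-of-moments dispersion
α_f = max((σ²_f − μ_f)/μ_f², 10⁻⁸) on normalized counts, per-condition NB
means fitted by Fisher scoring with log(s_j) offsets, and the Wald
statistic z = log₂FC / SE against a two-tailed normal reference.  Features
are called up/down at |log₂FC| ≥ 1 and −log₁₀ p ≥ 1.3.

**tRNA-half balance.**  Per isoacceptor and replicate, the 5′-half
percentage 100·c₅/(c₅+c₃), compared between conditions by unpaired t tests
with Holm–Šídák step-down correction (α = 0.05).

**Phenotype statistics.**  One-way ANOVA and Tukey–Kramer comparisons that
accept either raw per-embryo measurements or printed (n, mean ± SD)
summaries (the two are algebraically identical); two-sided Fisher's exact
tests (probability-mass definition, exact 2×k enumeration); and 2^−ΔΔCt
qPCR quantification with geometric-mean reference normalization.

**Simulator.**  `tsrnapipe.simdata` generates FASTQ libraries with the
full read structure, configurable class composition, condition-dependent
5′-half enrichment (default: Asp-GUC ×4, Glu-CUC ×3, Lys-CUU ×2.5,
Gly-GCC ×2 with unchanged 3′ halves), and a fragment-length shift
(24 ± 2 nt control vs 29 ± 2 nt treated), alongside morphometric tables
and phenotype contingency counts.  Ground truth is recorded for every
feature so recovery can be checked end to end.

## Worked example

Reconstructing the ceratohyal cartilage statistics from printed group
summaries (mean ± SD, n embryos):

```python
from tsrnapipe.phenostats import GroupSummary, tukey_hsd

groups = [
    GroupSummary("Ctrl", 14, 363.64, 18.96),
    GroupSummary("10MTX", 14, 192.99, 7.55),
    GroupSummary("50MTX", 26, 185.42, 8.71),
]
print(tukey_hsd(groups)[["group1", "group2", "mean_diff", "p_adj"]])
```

```
  group1 group2  mean_diff         p_adj
0   Ctrl  10MTX     170.65  5.995204e-15
1   Ctrl  50MTX     178.22  5.995204e-15
2  10MTX  50MTX       7.57  1.469764e-01
```

Both treatment doses shorten the ceratohyal with adjusted p < 0.0001; the
two doses do not differ from each other.

A full simulated 3-vs-3 study through the sequencing pipeline:

```python
from tsrnapipe import pipeline, simdata

refset = simdata.simulated_refset_with_halves()
samples = pipeline.simulate_study(refset, seed=1, n_replicates=3, n_reads=20_000)
res = pipeline.analyze_samples(samples, refset)

print(res["trna_length_medians"])
print(res["de_halves"].loc["tRNA-Asp-GUC.5p", ["log2fc", "p_value", "call"]])
```

```
{'control': 24, 'treated': 29}
log2fc     1.922056
p_value    0.010703
call             up
```

The tRNA-fragment length medians shift from 24 nt (control) to 29 nt
(treated), and the simulated 4-fold enrichment of the Asp-GUC 5′ half is
recovered as log₂FC ≈ 1.92 and classified "up"; its 3′ half stays "ns".

The same pipeline is available from the shell:

```bash
tsrnapipe run -o outdir --seed 1          # full pipeline, default config
tsrnapipe pheno tukey summaries.tsv --summary-mode
tsrnapipe pheno fisher 10 0 0 10          # two-sided exact test
```

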