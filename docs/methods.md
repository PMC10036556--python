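# Methods

This note documents the models and procedures implemented in `tsrnapipe`,
the parameters that matter, the numerical conventions, and the limits of
what the synthetic-data validation can show.

## Reference model and tRNA halves

The pipeline aligns against a transcript-level reference of mature sncRNA
sequences rather than a genome: small RNA fragments are intron-free and
contained within their parent transcripts, so transcript coordinates are
sufficient and keep the artifact self-contained.  Internally all intervals
are 0-based half-open; the GTF writer emits 1-based inclusive coordinates
and the BED writer 0-based half-open ones, and both readers invert their
writers exactly.

Stress-induced tRNA cleavage falls in the anticodon loop, so each tRNA of
length L with anticodon start a (0-based) is split after the middle
anticodon nucleotide: 5′ half = [0, a+2), 3′ half = [a+2, L).  When the
anticodon position is unknown the split falls at ⌊L/2⌋.  The split rule is
configurable (`anticodon_mid`, default, or `midpoint`) because the exact
half boundary is a modelling choice, not an observable: downstream 5′/3′
percentages depend on it, and users with coverage-derived boundaries can
supply their own features through the GTF/BED interfaces.  The two halves
always partition the tRNA exactly.

## Read model and trimming

Each raw read is `[4 random nt][insert][6 random nt][3′ adapter…]`,
truncated at the sequencer read length.  The random flanking nucleotides
are ligation spacers; they are removed and never used as UMIs (the
pipeline performs no deduplication).  Adapter search uses standard
3′-adapter semantics: the leftmost position where a prefix of the adapter
(≥ 5 nt overlap) extends to the read end with ≤ 10 % mismatches over the
matched span; reads without an identifiable adapter, or shorter than 15 nt
after trimming, are discarded.  The two mode-specific filter chains
(sncRNA: ≥ 19 nt after random-nt removal; halves: 3 further nt clipped
from the 3′ end of every read, then ≥ 15 nt) are kept as separate,
configurable stages.  The trim report accounts for every input read
exactly once, and the halves chain is by construction the sncRNA chain
with its length floor disabled, followed by the extra trim and re-filter.

## Alignment

Ungapped, sense-strand, full-length placements with at most one mismatch
(configurable).  The implementation indexes all reference 7-mers and takes
two non-overlapping seeds per read; by the pigeonhole principle a read of
≥ 15 nt with ≤ 1 mismatch has at least one exact seed, so the candidate
set is complete and the search is exactly equivalent to an
exhaustive-offset scan (a property the test suite asserts against a
brute-force oracle).  `N` matches nothing and counts as a mismatch.  All
placements at the minimum mismatch count are reported and a read with n
placements contributes 1/n wherever it is counted.  Antisense placements
are not searched: the library protocol is stranded.

## Counting, RPM, coverage, length medians

A placement is assigned to a feature when ≥ 50 % of the read lies inside
it (configurable).  The 5′/3′ half pair of one tRNA is mutually exclusive:
the half containing the majority of the read's bases wins, ties going to
the 5′ half; both the fraction and the tie direction are parameters
because half percentages are sensitive to them.  Total assigned count
equals the number of assigned reads (conservation, tested).

RPM uses as denominator the reads assigned to the functional sncRNA
categories (tRNA, rRNA incl. mitochondrial, miRNA, snRNA, snoRNA);
miscellaneous RNA is excluded from the denominator.  Coverage is a
per-base sum of 1/n weights (bin size 1, no smoothing), optionally scaled
to RPM.  Length distributions are 1/n-weighted; the median is the lowest
length whose cumulative weight reaches half the total, so even-mass ties
resolve downward and medians are reproducible integers.

## Differential abundance

The DE procedure is a deliberately simplified negative-binomial Wald test
in the style of count-based RNA-seq tools:

* **Size factors** — median-of-ratios: s_j = median over features, with
  all-positive counts, of k_fj / (∏_j k_fj)^{1/m}.  The median is taken on
  the linear ratio scale (this matters for even feature counts).
* **Dispersion** — method of moments on normalized counts across all
  samples: α_f = max((σ²_f − μ_f)/μ_f², 10⁻⁸), using the population
  (maximum-likelihood) variance.  With only a handful of replicates the
  unbiased-variance variant is markedly noisier and drags the Wald test
  below its nominal level (empirically ~0.025–0.03 rejection at p < 0.05
  under a 3 vs 3 null), whereas the population-moment variant keeps the
  empirical type-I error near 0.05–0.07.  There is no shrinkage toward a
  fitted mean–dispersion trend, no independent filtering and no outlier
  handling, so results are method-comparable, not numerically identical,
  to shrinkage-based tools.  Because the variance is pooled across
  conditions, a true effect inflates α_f and the test grows conservative
  for strongly perturbed features — a deliberate trade against
  anticonservativeness at n = 3.
* **Fit** — per-condition NB means with known α_f, Fisher scoring on
  β = log q with the size factors as offsets (score Σ(k−μ)/(1+αμ),
  expected information Σ μ/(1+αμ)); log₂FC = (β_t − β_c)/ln 2 with
  SE = √(1/I_t + 1/I_c)/ln 2 and a two-tailed normal p value.  Features
  with all-zero counts are `untested`.  A condition with all-zero counts
  drives its information to zero and the Wald statistic toward zero — such
  features come out non-significant rather than infinitely changed, which
  is conservative but avoids unstable infinite fold changes without
  shrinkage.
* **Calls** — up/down at |log₂FC| ≥ 1 and −log₁₀ p ≥ 1.3 on the raw p
  value; a Benjamini–Hochberg column is emitted for reference but does not
  enter the call.

## tRNA-half percentages

Per isoacceptor and replicate, percent5 = 100·c₅/(c₅+c₃) over the summed
half-feature counts; undefined cells (no 5′+3′ reads) are dropped.
Conditions are compared by unpaired two-tailed t tests (pooled variance by
default; Welch available) with Holm–Šídák step-down adjustment: with raw p
sorted ascending, the rank-i bound is 1 − (1 − p_(i))^{m−i+1}, adjusted
values are the running maximum clamped at 1, and tied raw p values share
the larger adjusted value.  Zero-variance ties with equal means give t = 0
and p = 1.

## Phenotype statistics

* **ANOVA / Tukey–Kramer from summaries** — SS_between is computable from
  (n, mean) alone and SS_within = Σ(n−1)·sd², so printed summaries carry
  exactly the information the tests need; raw-data mode computes the
  summaries first and therefore agrees to machine precision.  Tukey–Kramer
  handles unequal n with q = |Δmean| / √(MSE/2·(1/n_i + 1/n_j)) referred
  to the studentized-range distribution with (k, N−k) parameters.
  Printed "mean ± x" values are interpreted as mean ± sample SD by
  default, with an explicit SEM entry point (`GroupSummary.from_sem`),
  since published figure legends label spread inconsistently.
* **Fisher's exact** — two-sided by the probability-mass method (sum of
  fibre tables no more probable than observed, relative tolerance 10⁻⁷
  for floating-point ties), the convention of common statistical software;
  tail-doubling is available as an option.  2×k severity tables (normal /
  mild / strong) are enumerated exactly over the margin-fixed fibre for
  totals ≤ 200; larger tables are refused with advice to collapse
  categories.
* **2^−ΔΔCt** — the per-sample reference level is the arithmetic mean of
  the reference-gene Ct values, identical to the geometric mean of their
  linear quantities; ΔΔCt is taken against the mean ΔCt of the control
  condition and folds are rescaled so the control mean fold is exactly 1.

## Synthetic data: what it does and does not emulate

The simulator reproduces the *statistical structure* the analysis relies
on: class composition dominated by rRNA- and tRNA-derived fragments
(default weights rRNA 0.39, mt-rRNA 0.06, tRNA 0.37, miRNA 0.08, snRNA
0.04, snoRNA 0.03, misc 0.03 — free parameters, since real per-class
proportions are library-dependent), ten equally abundant isoacceptors,
3′-half relative weights of 0.25 (0.02 for Glu-CUC/Glu-UUC/Gly-UCC, whose
3′ halves are nearly undetectable in sperm, and 1.5 for the 3′-dominant
Ser-GCU), treated-condition 5′-half enrichments (Asp-GUC ×4, Glu-CUC ×3,
Lys-CUU ×2.5, Gly-GCC ×2) with 3′ halves kept at the control length model,
and fragment lengths as rounded clamped normals — 24 ± 2 nt (control) vs
29 ± 2 nt (treated) for 5′ halves, 22 ± 3 vs 24 ± 3 for rRNA fragments —
which reproduce the 24 → 29 nt median shift of tRNA-mapped reads.
Sequencing error is a uniform 10⁻³ per-base substitution; qualities are
constant because the pipeline never reads them.

Reference sequences are random, seeded stand-ins with realistic lengths
(synthetic, not biological sequences).  The simulator therefore does not
emulate: real tRNA sequence families and their shared k-mers (real
multimapping is heavier), CCA tails and nontemplated additions, indels,
PCR duplication, quality degradation, or ligation biases.  Passing
recovery tests consequently demonstrates the *correctness of the
computation* under the assumed generative model, not pipeline robustness
to every artefact of real libraries.

## Problem sizes and numerical conventions

Default validation runs use 3 + 3 libraries of 20,000 reads (the
simulation study), 2,000 features for the null calibration of the Wald
test, and 500-read oracle comparisons for alignment — sizes chosen so the
whole suite runs comfortably on a laptop while leaving all Monte-Carlo
margins wide (the length medians and fold-change recovery are stable
across seeds at these sizes).  Fisher-scoring iterations cap at 60 with
step clamping to ±5 on the log scale and β ∈ [−50, 50]; convergence
tolerance 10⁻¹²; dispersion floor 10⁻⁸.  All simulation randomness flows
through a single seeded NumPy generator per library, with per-library
seeds derived from the run seed, so identical configurations are
byte-identical.

## Known limitations

* DE output is not numerically comparable to shrinkage-based tools,
  especially at low counts or for features with one all-zero condition.
* The aligner is designed for transcript-scale references (a few kb of
  total sequence per class); it is exact but not engineered for
  genome-scale inputs.
* The 2×k exact test's fibre enumeration grows quickly with k and totals;
  beyond the guarded limits, collapse categories or use asymptotic tests.
* Half-boundary assignment (majority overlap, ties to 5′) is a convention;
  percentages for isoacceptors with many boundary-spanning reads shift
  under other conventions, which is why both knobs are exposed.
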