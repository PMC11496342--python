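# Methods

This note documents the models, conventions and design choices behind
crown-ocr, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and gene models

All internal coordinates are 0-based, half-open (BED convention); GFF3 input
(1-based inclusive) is converted on read. The TSS of a plus-strand gene is
`span.start`; of a minus-strand gene `span.end − 1` (the last base). The
promoter-gene interval [TSS − 5 kb, TTS + 1 kb] and the promoter
[TSS − 5 kb, TSS] are taken in transcription direction, i.e. mirrored in
genome coordinates for minus-strand genes: a strand-blind window would place
minus-strand promoters inside the gene body. Windows are clipped at
chromosome edges, never discarded, so genes near contig ends keep a (shorter)
window; a window that clips to nothing is an error. Transcript-level models,
alternative TSSs and UTRs are out of scope.

## OCR merging

Merging is the transitive closure of strict interval overlap (≥1 shared
base): bookended intervals ([100,200) and [200,300)) do **not** merge. This
matches common peak-merge semantics and makes the operation exactly testable
against a union-find oracle. "Present in at least one replicate" is a plain
union-merge; a `min_support` parameter (default 1) exposes stricter consensus
but is not part of the default analysis. Support is conserved: the sum of
OCR supports equals the number of input peaks, for every merge, including
marginal sets (pooling pre-merged variant sets is provably identical to
merging the pooled raw peaks, because the hull of an overlap chain overlaps
exactly what its members overlap — the tests verify this equality). OCR ids
are assigned in (chromosome, start) order, so outputs are reproducible.
Read subsampling to equal depth happens upstream of peak calling and is
outside this package's inputs. Reproducibility between two OCR sets is
100 × (OCRs of the smaller set intersecting the larger) / |smaller set|;
it is undefined (an error) for empty sets.

## Gene context

`over_TSS` means the OCR contains the single TSS base; `promoter` means the
OCR lies wholly on the upstream side of the TSS; everything else overlapping
the promoter-gene interval is `gene_body`. The per-gene class uses the
precedence over_TSS > promoter > gene_body. The precedence direction was a
genuinely open choice; proximity to the strongest expression signal (TSS
coverage associates with the highest expression) is the minimal consistent
rule, and it makes the three classes a partition of the accessible genes —
an invariant the suite asserts on every synthetic study. Coverage percent is
computed on the union of OCR overlaps, so it is invariant to how OCRs are
split. TSS-relative offsets are reported on the transcription axis (negative
= upstream); for minus-strand genes, genomic coordinates are reflected about
the TSS, which keeps the core-promoter pile-up of OCR starts in [−500, 0]
comparable across strands.

## Expression and differential expression

FPKM uses the raw column sum as library size (no effective-length
correction), and a gene is "expressed" when its mean FPKM across **all**
samples is ≥ 0.5 (inclusive). The mean is over all samples rather than per
variant because the flag describes the experiment as a whole; a per-variant
variant of the flag is a trivial caller-side restriction of the FPKM table.

`test_de` is deliberately a lightweight stand-in for a full NB-GLM engine,
because the pipeline's scientific content is the thresholds and the
integration, not the DE machinery:

* median-of-ratios size factors (geometric-mean reference over genes positive
  in all samples);
* per-gene method-of-moments dispersion from pooled within-group variances,
  `alpha = (s² − m)/m²`, clipped to [1e-8, 10];
* empirical-Bayes-style shrinkage in log space toward the genewise **mean**
  of the raw estimates, with prior weight 40 against the residual df (4 at
  3 vs 3). The heavy shrinkage is intentional: with 2–3 replicates per group
  the per-gene estimate carries almost no information, and the mean (not the
  median) of the raw moment estimates is the approximately unbiased center;
* a Wald z on the difference of log group means with delta-method variance
  `(1/m + alpha)/n` per group, normal two-sided p, pseudocount 0.5 in the
  fold-change logs.

The suite calibrates this test: under a null NB simulation (2000 genes,
3 vs 3, dispersion 0.05) the empirical type-I error at α = 0.05 must fall in
[0.03, 0.07], and a planted log2FC of 3 must be recovered with median error
≤ 0.5. DEG calling applies `base_mean ≥ 5` (normalized mean over the
contrast's samples — the closest operational reading of a mean-expression
floor "estimated in" a DE engine), `padj < 0.05`, and strictly `|log2FC| > 2`.
Contrast orientation: `test_de(matrix, (ref, alt), factor)` reports log2FC of
`alt` relative to `ref`; the CLI syntax `--contrast temperature:HT,C` means
"HT versus C". Shrunken-LFC estimators and multi-factor interaction GLMs are
out of scope.

## Integration

Accessibility status of a gene in a variant is its OCR count within the
promoter-gene interval (gene-level, not raw peak counts). The lose/gain
definitions (≥1→0, 0→≥1) make change classes a partition of all genes and
exactly antisymmetric under swapping the variants — both asserted. The
"losing genes are more likely to be down- than up-regulated" claim is
operationalized as a conditional 2×2 exact test restricted to DEGs of the
same contrast (rows lose / not-lose, columns down / up), reporting the
cross-product odds ratio, a two-sided Fisher p, and a 95% CI from the
Haldane–Anscombe (+0.5) corrected log odds ratio; the symmetric gain table is
reported alongside. The choice of an explicit exact test (rather than a
qualitative statement) is this package's, made to render the association
assertable. Coverage–expression association is summarized per 10% coverage
bin and per gene class, with a Spearman correlation of bin midpoint versus
median FPKM as the trend statistic (defined as 0 for degenerate inputs).

## Enrichment

Annotation arrives as a flat term→gene map assumed pre-propagated; the
ontology DAG, elim/weight algorithms, and pathway databases are out of scope.
The FWER procedure is min-p randomization: `n_random` (default 1000) gene
sets of the study-set size are drawn uniformly without replacement from the
universe; FWER(t) is the fraction of draws whose minimum hypergeometric p
across all terms is ≤ the observed p of term t; terms with FWER < 0.01 are
flagged. This controls the family-wise error in the strong sense of the
randomization null and reproduces bit-for-bit for a fixed seed. The
randomset count and estimator details are this package's defaults. The
implementation is vectorized (term-membership matrix × indicator matrix);
the suite checks null calibration (flagged fraction ≤ 0.01 + 3 MC SE over
200 replications) and single-term consistency (FWER → p as n_random grows).

## Synthetic-study generator

The generator emulates the target design: 3 genotypes × 2 time points × 2
temperatures, 2 ATAC + 3 RNA replicates (24 peak files, 36 count columns).
Genes (1–5 kb, random strand) are spaced ≥ 12 kb so promoter-gene intervals
never overlap — gene-level truth is then unambiguous; overlapping genes are
exercised separately with hand-built micro-fixtures. Per gene the truth
draws: baseline accessibility (p = 0.35 under control, near the real study's
marginal proportion), loss under heat (p = 0.20 among accessible), gain under
heat (p = 0.25 among inaccessible), an OCR placement (promoter/over_TSS/
gene_body at 0.37/0.48/0.15, following the observed gene-class split), and a
regulation label. Down-regulation couples to accessibility loss on the odds
scale: odds(down | lose) = `coupling_or` × odds(down | not lose), with
baseline down/up rates of 0.20. These planted rates are denser than a real
full-genome contrast would show; at the desk-scale default of 2000 genes they
keep every cell of the lose × regulation cross-table large enough that the
generator's recovery contract — odds-ratio estimate within [2, 8] when
`coupling_or` = 4, run by run — holds, which is what the recovery tests
assert. Peak emission: each truly accessible (gene, variant) yields a peak
per replicate with probability 1 − `peak_noise`, jittered ±100 nt (true
placements keep ≥150 nt margins to class boundaries, so jitter cannot change
the class); spurious peaks land only in intergenic slots that cannot touch
any promoter-gene interval. Counts are negative-binomial (dispersion 0.05)
with log-normal baselines, an accessibility-linked mean shift and a
coverage-linked slope (so accessible and better-covered genes express more),
per-sample library factors, and 2^(±3) fold changes on heat samples of
regulated genes.

With the default expression baseline nearly all genes pass the FPKM ≥ 0.5
flag; the expressed-vs-accessible contrast is exercised non-vacuously in the
tests at a lowered baseline. What the generator does **not** emulate: read-
level artifacts (fragment-size, Tn5 bias, mappability), overlapping genes,
genotype- or time-specific regulation, dispersion trends with expression, and
batch effects. Passing tests therefore demonstrate correctness of the
pipeline's set algebra, classification, calibration and recovery under the
stated generative model — not robustness to those real-data features.

All randomness flows from one master seed through named `SeedSequence`
spawns (annotation, truth, peaks, counts, terms); fixtures and pipeline
outputs are byte-identical across reruns with the same seed, and the pipeline
is single-threaded by contract.

## Problem sizes

Simulation-based checks run at deliberately desk-scale sizes chosen as the
smallest that make the statistics informative: 2000 genes for DE and FWER
calibration and for the 50-seed coupling-recovery envelopes, 500 genes for
accessibility-recovery rates, 1000 random instances (≤200 peaks) for the
merge oracle, and exhaustive hypergeometric checks to N = 25. The acceptance
script uses the full default study (2000 genes, 24 + 36 samples) end to end.
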