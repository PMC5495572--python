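# Methods

## Scope

`exactrna` implements a desk-scale, fully exact-match RNA-seq
quantification pipeline for two-condition comparisons, the delta-Ct qPCR
arithmetic used to validate such comparisons, and a ground-truthed
simulator that generates every input the pipeline consumes. The design
goal is a small, auditable chain of primitives whose every step has an
independent oracle, not a competitor to genome-scale aligners.

## Mapping model

Reads are single-end (100 nt canonically). Each read is trimmed by 2 nt
at both ends and the remaining core split into three equal parts — for a
100-nt read, three 32-mers at read offsets 2, 34 and 66. Any length with
(L − 4) divisible by 3 and parts ≥ `min_part` (default 20) is accepted;
other reads are skipped and counted, never reported as unmapped.

Parts are looked up verbatim in a suffix array over the sentinel-joined
reference. A placement candidate exists where all three parts hit the
same sequence and strand at exact spacing k — equivalently, where the
whole trimmed core occurs verbatim. A read is `unique` with exactly one
candidate genome-wide (both strands), `multi` with several, `discordant`
when some orientation had all three parts hitting but never collinearly,
and `unmapped` otherwise. Exact matching is all-or-nothing per part: one
substitution inside any part destroys that part's hit, so a read
overlapping a sequencing error is (by design) lost rather than placed
approximately. Substitutions in the 2-nt flanks are invisible because
the flanks are never matched.

The suffix array is built by prefix doubling (O(n log n)); lookup is
binary search over suffix prefixes. Sentinels sort below every base, one
per sequence, so matches cannot cross sequence boundaries (queries never
contain sentinel characters). N in the reference matches nothing and
queries containing N return no hits — "exact" is taken literally.
Multi-mapping reads are dropped from coverage: with no stated policy,
dropping is the conservative, deterministic choice.

## Expression

Unique placements add depth 1 over their full trimmed span (96 nt for
100-nt reads). Gene expression is the **median of per-base depth** over
the gene's annotated bases (even counts: mean of the two central order
statistics; multi-interval genes: median over the concatenated bases).
The whole trimmed span is used rather than the three parts separately —
the parts are adjacent by construction, so the distinction would only
matter for discordant reads, which are excluded anyway. A base shared by
two overlapping genes counts toward both medians. No FPKM/TPM-style
length normalization: median depth is already a per-base quantity.

## Normalization and differential expression

Samples are quantile normalized: each column is mapped onto the
across-sample mean of order statistics; ties within a column receive the
mean of their tied target quantiles, making the transform deterministic
and idempotent.

**Noise estimation.** All matrix values are pooled, transformed by
log2(1 + x), smoothed with a Gaussian kernel (Silverman bandwidth,
512-point uniform grid), and the density argmax is transformed back.
With a large cohort of low/silent genes the pooled density peaks at the
low-expression floor, and that floor is "the noise". Estimation happens
after normalization (recorded in the estimate's metadata); the transform,
bandwidth rule and grid are configurable. A degenerate (all-equal) input
returns that value with a `degenerate` flag. One global noise value is
shared by all genes and both groups.

**Regularized fold change.** Per gene,
`lgFC = log2((mean_case + noise) / (mean_ctrl + noise))`, group means
taken on the normalized matrix. The additive noise term bounds
|lgFC| ≤ |log2(case/ctrl)| with shrinkage increasing in noise, and a
gene silent in both groups gets exactly 0 — low-expression genes cannot
top the fold-change ranking. "lg" is log2 throughout (the heat-map scale
is explicitly log2); the base is configurable. The default orientation
reports up-regulation in the case group as positive; an alternative
`printed` orientation (control over case) negates the sign.

**Outliers.** Samples are compared by pairwise Pearson correlation of
their log2(1 + x) columns. Exclusion is greedy-iterative: while any
sample's mean correlation to the other *retained* samples is below the
threshold (default 0.8), the worst sample is removed and similarities
recomputed. One-shot flagging fails the obvious test case — a single
shuffled impostor drags three perfect replicates' mean correlation to
≈ 0.67, flagging everyone — whereas iterative removal flags exactly the
impostor. At least two samples are always retained; with fewer than
three samples the report is marked not applicable.

**Heat-map standardization.** Panel genes' lgFC values are clipped to
[−1.5, +1.5] (configurable) in panel order; panel genes absent from the
table are reported, never silently dropped. Figure output is optional
and never load-bearing.

## qPCR

Replicate Ct values are averaged arithmetically on the Ct scale
(replicate outliers are not rejected; no rule is assumed). Relative
expression within a sample is `2^-Ct(target) / 2^-Ct(reference)` —
perfect efficiency, one cycle = one doubling — so sample-wide shifts
cancel through the reference gene. Condition fold change is the ratio of
condition means of per-sample relative expressions; this matches
per-sample dot plots and differs from 2^-ΔΔCt on condition-mean Cts only
under replicate imbalance. A paired mode computes per-pair ratios
(clutch-style pairing via `pair_id`) and averages them; the two modes
agree exactly when every pair has identical control values.

## Synthetic data

The simulator emulates a two-condition knockdown experiment at desk
scale. Defaults (the conditions the test-bed exercises):

| parameter | default | why |
|---|---|---|
| genes | 200, non-overlapping on one chromosome | enough rank resolution for quantile normalization; minutes-scale runtime |
| gene length | U(400, 800) bp, 100 bp spacers | short-transcript scale; ≥ 4× read length |
| read length | 100 nt, single-end | canonical geometry (3 × 32 after trimming) |
| baseline expression | log-normal, log2 mean 5, sd 1 | skewed expression typical of bulk RNA-seq |
| noise floor | 50% of genes at relative weight 1 | most annotated genes are off/low in a given tissue; makes the pooled density peak the floor the estimator must find |
| planted DE | 20 genes at log2 FC ±2, placed in the upper-middle of the baseline distribution | well-expressed but not top-ranked — quantile normalization has no headroom at the extreme top rank, which would squash any planted change regardless of depth |
| depth | ~30× mean over gene bases | read counts per gene multinomial over expression-weighted gene lengths |
| replicates | 3 per condition | |
| substitution errors | 0.001/base i.i.d. | loses ≈ 9% of reads to exact matching; uniform qualities |
| qPCR | triplicates, Ct sd 0.2 cycles, offset 30, 6 samples/group, reference gene `rpp0` at fixed level | Ct = offset − log2(expression) + noise |

Base composition is i.i.d. uniform; in repeat-free mode the chromosome
is resampled until every 32-mer is unique across both strands, making
error-free placement provably unambiguous. Read starts are uniform
within the gene (no positional bias — median coverage is insensitive to
edge effects at this scale), strands uniform. Every read's source gene,
position and strand are recorded in a ground-truth table; all simulators
are pure functions of (config, seed).

What the simulator does **not** model: GC/positional bias, quality-score
structure, splicing, indels, library-size heterogeneity, biological
replicate dispersion beyond multinomial sampling. Passing recovery tests
therefore demonstrates the pipeline's arithmetic and its behavior under
sampling noise and uniform errors — not robustness to the full error
structure of real sequencing data.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; SAM output converts at
  the boundary. BED input is 4+ columns.
- Quantile-normalization ties: mean of tied target quantiles.
- DE table ordering: |lgFC| descending, ties by gene id (stable).
- `noise ≤ 0` is rejected (division-by-zero hazard); zero-depth genes
  are fine (the regularizer keeps everything finite).
- Empty FASTQ → empty placement list, all-zero stats. Malformed records
  are reported with their 0-based record index.
- Index serialization is a versioned JSON blob; loaders reject version
  mismatches and corrupt suffix tables.

## Problem sizes

The default test-bed (200 genes, 6 samples, ~38k reads/sample) maps and
quantifies in well under a minute on one core; the oracle comparisons use
a 50-kb reference and 1000 reads. These sizes were chosen as the
smallest at which every statistical property of interest (rank-based
normalization, density-peak noise estimation, outlier correlation
structure) behaves as it does at scale.

## Known limitations

- Exact matching discards every read with an error inside the trimmed
  core; sensitivity falls geometrically with error rate.
- A single global noise value assumes a shared floor across samples.
- The outlier rule is correlation-based only; batch structure or
  condition imbalance can masquerade as (or mask) outliers.
- No p-values are attached to fold changes; ranking is by magnitude.
- qPCR assumes perfect amplification efficiency (no standard curves).
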