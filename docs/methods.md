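# Methods

`stagetx` implements the post-assembly analysis of a de novo life-cycle
transcriptome sampled at three stages — pre-competent larva, post-larva,
and adult — spanning settlement and metamorphosis.  It operates on three
input tables (a per-contig read-count matrix, a top-hit BLAST table with
query and subject lengths, and a contig-to-GO annotation table) and never
touches raw reads: trimming, assembly, read mapping and BLAST/annotation
execution are upstream of this package.

## Expression filtering

Without technical replicates, differential expression is defined by fixed
detection and fold cutoffs rather than statistical tests:

* **Detection**: a contig counts as reliably observed when it has at
  least `min_reads` (default 64) reads in at least one stage.
* **Stage-specific change**: a contig is selected when, for some stage
  `s`, the pseudocounted ratio between stage `s` and the arithmetic mean
  of the other two stages reaches `fold_threshold` (default 4) in either
  direction.
* **Transition change**: for an ordered stage pair, the later/earlier
  pseudocounted ratio ≥ 4 marks the contig up-regulated, ≤ 1/4 down.

Expression values for correlation are `log2(count + 1)`.  Fold ratios are
computed on pseudocounted raw counts, not on the log values: a fold
change is a ratio of expression levels, and the +1 both avoids division
by zero and matches the pseudocount used before the log transform.  The
arithmetic mean (not the geometric/log-scale mean) of the other two
stages is used; the stated rule is a ratio of count levels, and the
choice is echoed in the run header so downstream readers can see it.
Boundaries are inclusive: a ratio of exactly 4 is selected.

## Correlation profiles and clustering

Stage similarity is Pearson's r between the log2(count+1) vectors of the
filtered contig set.  95% confidence intervals use Fisher's
z'-transformation: `z' = atanh(r)` is treated as normal with standard
error `1/sqrt(n-3)`, so the interval is `tanh(atanh(r) ± z*/sqrt(n-3))`.
`z*` is the exact normal quantile (1.959964…), not 1.96 rounded; at the
reported precision the two are indistinguishable.

Stages are clustered by UPGMA on the rescaled distance `1 − r`.  Because
r can be negative, distances above 1 are legal and handled.  The merged
node's height is half the merge distance (the ultrametric convention),
cluster-to-cluster distances are size-weighted arithmetic means, and ties
are broken by lexicographic cluster-label order.  The implementation is
an explicit O(n³) agglomeration — stage counts are tiny — and is
cross-checked in the tests against SciPy's average-linkage on random
instances.  Trees serialise to Newick with branch lengths derived from
the ultrametric heights.

## GO enrichment

For each transition, the up- and down-regulated annotated contig sets are
tested separately against the annotated reference (the non-redundant
all-stages contig set intersected with the annotation table; test-set
contigs are excluded from the reference column of each 2×2 table, the
standard term-enrichment convention).  Every term annotating at least one
test-set contig gets a two-tailed Fisher exact test; p-values are
corrected per (transition, direction) family with Benjamini–Hochberg and
flagged at `q ≤ α` (default 0.05).  Because the test is two-tailed, a
strongly enriched term can also reach significance as *depleted* in the
opposite direction's family; such dual hits are resolved to the
smaller-q direction with a logged warning.  GO ancestor propagation is
deliberately not performed — terms are tested exactly as annotated.

The cross-transition comparison counts significant terms by direction in
each of two transitions, forms the 2×2 up/down table, reports integer
percentages of up-regulated terms, and attaches a two-tailed Fisher
exact p.

## Assembly quality assessment

* **N50**: contig length at which the cumulative length of
  descending-sorted contigs first reaches half the assembled bases.
* **Ortholog hit ratio (OHR)**: contig length divided by its top BLAST
  match's length; summarised by mean, corrected (n−1) sample SD, and the
  box-plot percentiles (5/10/25/50/75/90/95, linear interpolation).  The
  full contig length is used, not the aligned region.
* **Redundancy** — two senses.  *Broad*: percentage of hit contigs whose
  subject is shared with another contig.  *Narrow*: per subject, contigs
  are grouped into connected components by subject-interval overlap
  (≥ 1 shared base by default; configurable), each component read as one
  distinct duplicate gene; components beyond the first per subject each
  count one redundant contig.  Narrow ≤ broad holds for any overlap
  threshold.  Intervals are 1-based inclusive as in tabular BLAST;
  component construction uses a sorted sweep, which is exact for
  intervals.
* **Non-redundant reference**: per subject, only the overlap component
  containing the longest contig is kept (ties by contig id); other
  components are treated as extra fragments of the same gene and removed.
  Contigs without hits are always retained.
* **Saturation**: each fraction of the default 12.5%–87.5% grid draws its
  own independent without-replacement subsample of the pooled reads (the
  draws are not nested) and a pluggable evaluator maps the subsampled
  counts to (contigs with significant hits, N50).  Production users can
  wire a real assembly+search pipeline; the tests use the synthetic
  emulator described below.
* **Depth normalization**: every stage column is downsampled to the
  smallest stage total by an exact without-replacement multivariate
  hypergeometric draw, so totals match exactly and per-contig proportions
  are preserved in expectation.  This thins mapped counts rather than
  resampling raw reads and re-assembling; at desk scale it is the
  faithful stand-in for the read-level procedure and is flagged as such
  in the run header.

## Synthetic data generator

The generator plants known truth at every level the pipeline consumes.

**Counts.**  Per-gene baselines are lognormal (median `base_mean` = 64
reads, spread 2.5 log2 units — a wide dynamic range in which roughly
half the genes clear the 64-read detection cutoff, as is typical when a
deep reference set is filtered).  Counts are negative binomial with size
`dispersion` = 8 (biological CV² = 1/8); `dispersion = inf` gives the
Poisson limit.  Planted effects multiply `(mean + 1)` by `effect_fold`
(default 8, comfortably past the 4-fold rule) as *step functions* in
life-cycle order: a transition-up gene is elevated in every stage after
its transition, a transition-down gene in every stage before it, so each
planted effect is confined to its own transition.  Default planted
fractions are asymmetric — 10% up / 5% down across the first
(settlement/metamorphosis) transition, 2.5% up / 6% down across the
second — giving the first transition more change and an up-dominated
direction profile, and the second less change dominated by
down-regulation; stage-specific genes (15%) get one elevated stage.
This produces the characteristic correlation ordering
r(post-larva, adult) > r(pre-competent, post-larva) > r(pre-competent,
adult) and a stable UPGMA topology joining the two post-settlement
stages first.  Per-stage depth factors (1.0, 0.85, 1.05) emulate the
10–15% library-size inequality of real stage libraries, which is what
the normalization robustness check exercises.

**BLAST structure.**  One subject per gene; contig lengths are lognormal
around 700 bp (≥ 300 bp), and subject lengths are set from a
Beta(1.4, 2.6) target OHR (mean ≈ 0.35, matching typical de novo
assemblies of non-model invertebrates).  A fraction of genes (10%) get
extra fragment contigs whose subject intervals either share coordinates
with the primary contig (overlapping — reads as duplicate genes under
the narrow definition) or occupy disjoint slots (non-overlapping —
fragments of one gene), so both redundancy definitions have analytic
expected values computable from the plan.

**Annotations.**  Background terms annotate every gene with probability
0.05; each planted term annotates its target (transition, direction)
gene set at `enrichment_ratio` (10×) that rate, capped at 1, topped up
deterministically to a minimum annotation count.  Only primary contigs
carry annotations; fragment contigs share their gene's subject and are
collapsed by the non-redundant reference anyway.

All randomness is explicit: every generator takes a seed, `generate_bundle`
derives four sub-seeds from one master seed via `SeedSequence`, and
identical seeds give byte-identical output files.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: raw reads and read-level error,
assembly artefacts (chimeras, allelic splits), rRNA or symbiont
contamination, paralogy beyond the overlapping-fragment device,
correlated GO terms (terms are drawn independently, so the BH
correction's behaviour under strong term-term dependence is untested),
and any distributional mismatch if real counts are not negative
binomial.  The count model itself is a stand-in: nothing upstream
specifies a distribution for mapped counts, and NB is the standard
overdispersed choice.

## Numerical and degenerate-input choices

* Fold boundaries inclusive; direction antisymmetric under stage-order
  reversal (verified end-to-end in tests).
* Pearson r is undefined (error) for constant vectors; Fisher intervals
  require |r| < 1 and n ≥ 4.
* Fisher exact tables with a zero margin return p = 1 with a logged
  warning rather than erroring mid-run.
* Top-hit selection: lowest e-value, ties by highest bit score, then
  lexicographic subject id; e-value cutoff 10⁻⁵ applied at parse time.
* Reversed subject coordinates (minus-strand hits) are normalised to
  start ≤ end and flagged; writers re-emit the original orientation so
  round trips are identities.
* Parsers reject rather than coerce, and name the offending line.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
3000-gene bundles (the generator default, a deliberately compact
assembly), exhaustively verify the exact test against an enumeration
oracle for every 2×2 table with total ≤ 20, and estimate planted-term
recovery and null-term false discovery over 20 (tests) or 10 (script)
seeds — sizes at which every statistical property checked has ample
power while the whole suite stays fast.

## Known limitations

* Enrichment direction assignment (separate up/down runs, dual hits to
  the smaller q) is one of several defensible conventions; output
  metadata records it.
* The redundancy component-counting convention (components − 1 per
  subject) follows from reading each overlap component as one gene;
  other conventions exist, and the overlap threshold is configurable.
* Saturation with the synthetic evaluator characterises the subsampling
  machinery, not any real assembler's behaviour.
* No plotting beyond the tabular outputs; heat maps and box plots are
  left to downstream tooling.
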