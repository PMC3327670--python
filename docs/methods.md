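# Methods

## Scope and data model

The pipeline starts from *alignment intervals*, not raw sequence: a
6-column BED-like TSV per sample (chrom, start, end, read_id,
mismatches, strand) plus a manifest assigning samples to the four
conditions (sham, TAC, sedentary, exercise).  A read is treated as
multi-mapped when its read_id occurs on more than one line.  Alignment,
quality trimming and isoform-level deconvolution are out of scope, as
are de novo motif discovery and proprietary network analysis.

All coordinates are 0-based half-open internally (BED convention); the
GTF-like reader converts on input.  A gene is its *exon model* — the
union of its exon intervals; the union length is the RPKM denominator
and the strand-aware outermost coordinate is the TSS.

## Quantification

Reads surviving the filters (uniquely mapped, fewer than two
mismatches, optionally not mitochondrial — the chrM filter is a named
chromosome, default on) are assigned to at most one exon per gene: the
exon with the largest base-pair overlap, ties to the smaller exon
start.  The gene count is therefore exactly the sum of its exon counts,
and a read can count once in each of several genes only where genes
themselves overlap.  This rule is a design choice — any single-count
rule would do — picked because it keeps the gene/exon count relationship
an exact testable invariant.

RPKM uses the post-filter library size of each sample.  The log view is
`log2(1000*RPKM + c)` with pseudocount `c = 1` (configurable) so zero
counts map to 0.  A gene is "expressed" in a condition when any
replicate reaches the 2 RPKM floor (`any_replicate`, default) or when
the condition mean does (`group_mean`); both readings of the floor are
provided because the phrase "detected at least once for each replicate"
is genuinely ambiguous.

## Differential expression

Equal-variance two-sided Student's t on raw replicate RPKM (Welch
available via `equal_var=False`), df = n1+n2-2.  Degenerate limits are
pinned: identical constant groups give (t=0, p=1); zero pooled variance
with unequal means gives p=0.  Genes are tested when the larger group
mean reaches the floor (2 RPKM) — the floor's group semantics are also
ambiguous in the source design; max-of-means is the implemented reading
and is configurable.  Fold change is pseudocounted,
`(m_t + 0.25)/(m_c + 0.25)`: turned-on genes have near-zero control
means, so a raw ratio would be undefined; 0.25 RPKM is an order of
magnitude below the expression floor and negligible for any tested
gene.  Calls need `p < 0.05` and `|log_1.5 FC| >= 1`.  P-values are
deliberately raw (that is how the analysis this package reproduces was
reported); Benjamini–Hochberg is available but off by default.

Classifier definitions:

* **turned-on** — up-called in PAH, mean < 2 RPKM in sham *and* in
  exercise (when that arm exists), mean >= 2 RPKM in TAC.  Requiring
  low expression in both baseline-like arms is the stricter of the two
  published readings and is the one implemented.
* **opposite** — significant in both contrasts with discordant signs.

## Exon inclusion/exclusion

The contingency table contrasts an exon against the *rest of its gene*
(not the whole library), with replicates pooled within condition:

|               | control | treatment |
|---------------|---------|-----------|
| exon          | a       | b         |
| rest of gene  | c       | d         |

Pooling is deliberate: at n = 3 the per-replicate exon counts are too
sparse for a per-replicate exact test, and the exon-vs-gene framing
cancels gene-level differential expression so that a significant table
is a *usage* change.  Single-exon genes (c = d = 0) and genes with no
reads in one condition are not testable.  Exons enter testing at
>= 10 RPKM mean in at least one of the two compared conditions.

Two-sided Fisher exact p sums hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed one, with relative tolerance 1e-7 for ties; probabilities come
from a log-gamma evaluation (abs. error vs exact enumeration < 1e-13 over
all tables with total <= 60, checked exhaustively).  The Bayesian error
rate is the posterior probability that the apparent direction is wrong
under independent Beta posteriors with uniform priors,
`theta_ctrl ~ Beta(a+1, c+1)`, `theta_trt ~ Beta(b+1, d+1)`.  It is
computed by adaptive quadrature of the smaller tail,
`integral f_lo(y) * SF_hi(y) dy`, restricted to the 1e-16..1-1e-16
quantile bracket of the pdf factor (discarded tails < 2e-16), which
keeps extreme tables accurate without cancellation; a seeded Monte
Carlo method (`method="mc"`) serves as the stochastic alternative and
as the test oracle.  The exact error-rate formulation behind the
original analysis is not public; the sign-error posterior is this
package's documented interpretation of a credibility-style error
filter, and the quadrature is evaluated only for Fisher-significant
tables since the joint gate cannot pass otherwise.

Calls require Fisher p < 0.05, e <= 0.1 and a non-empty knownAlt label
set; direction is inclusion when pooled usage is higher under
TAC/exercise.  Type summaries weight an exon with k labels 1/k per
label so proportions sum to one.

## Pathway enrichment

Universe N = union of all GMT pathway genes; query genes outside it are
dropped before M is computed.  p is the one-sided upper tail
`P(X >= k | N, n, M)` (enrichment only).  A pathway is flagged
significant per category-record when `p < 0.05` and `k >= 5`; the
minimum-membership rule is applied per category, not per pathway
overall.  The heat matrix holds `-log10 p` for significant cells and 0
elsewhere; biological pathway groupings are user-supplied labels, never
computed.

## Motif occurrence

Upstream sequences are the 1,000 bp 5' of the TSS, strand-corrected and
clipped at contig edges.  Matching is exact IUPAC with no mismatch
allowance; a sequence `N` is matched only by a motif `N`.  An upstream
counts at most once regardless of occurrence count, and the reverse
complement is never scanned — both rules follow the occurrence
convention of the analysis being reproduced.  Enrichment is a one-sided
Fisher test of presence counts against an explicit, disjoint background
set; no default background is assumed because none was specified
upstream of this design.

## The synthetic study generator

`simulate_study` emulates the structure of the two-model design at desk
scale: 4 conditions x 3 replicates, single-end 36 bp reads, default 300
genes on two contigs (1–12 exons of 80–300 bp each, ~30% of exons
carrying one weighted knownAlt label, alternative promoters and
cassette exons most frequent) and 200,000 reads per sample — a full
pipeline run in seconds rather than hours.

Baseline expression is log-normal across genes.  Per sample, a gene's
count is negative-binomial with `var = mu + (bcv*mu)^2`; `bcv`, the
biological coefficient of variation between replicates, defaults to 0.1
— the canonical value for genetically identical model organisms such as
the inbred mice this design emulates.  Conditional on the gene total,
reads fall on exons multinomially by length x inclusion proportion:
biological noise is shared across a gene's exons, and exon usage is
binomial given the gene count, which is exactly the sampling model the
pooled Fisher test assumes — so the null false-positive rate of the
splicing cascade is nominal by construction.  Modelling extra
between-replicate usage noise (which would overdisperse the pooled
tables) is a known limitation, as are uniform read placement, flat
sequence content and the absence of junction reads.

Spiked signals, all recorded in a truth table the pipeline never reads:

* ordinary DEGs per contrast with fold changes log-uniform in [5, 9] —
  the magnitude of the strong inductions this design is built to
  detect; spiked genes have their baseline clipped upward so both group
  means clear the expression floor comfortably;
* turned-on genes: baseline relative expression ~1e-5..5e-5 (well under
  2 RPKM, expected counts near zero) induced to 0.05–0.15 under TAC
  only;
* opposite genes: one fold change applied up in one contrast, down in
  the other;
* 30 exon-usage events on labelled exons of multi-exon, well-expressed
  genes (at most one per gene): inclusion 0.25 -> 0.55 or 0.55 -> 0.25
  in one contrast (delta 0.3);
* one pathway packed with spiked DEGs; the consensus motif GGGAGGG
  planted (strand-aware) in the upstream of every turned-on and
  opposite gene.

Decoy reads (6% of the library: duplicated-id multi-mappers, 2-mismatch
reads placed inside exons, and clean mitochondrial reads) exercise the
alignment filters without contributing to any count.  Everything flows
from a single `numpy` generator, so a seed reproduces annotation,
genome, reads and downstream calls bit for bit.

What passing tests on this generator do *not* show: robustness to
mapping bias, 3' coverage decay, overlapping gene models at scale,
genuine usage overdispersion, or annotation error — all properties of
real data the generator does not attempt.

## Problem sizes and numerical conventions

The shipped validation uses the 300-gene, 4x3-sample, 200k-read
configuration throughout; the Fisher sweep is exhaustive over all
~6.3x10^5 tables with total <= 60, and the Bayes panel compares
quadrature to 10^6-draw Monte Carlo on 50 tables.  Ties in the
two-sided Fisher tail use relative tolerance 1e-7; quadrature
tolerances are 1e-14 absolute / 1e-10 relative; RPKM and fold-change
arithmetic is double precision throughout.  All thresholds (2 RPKM
floor, 10 RPKM exon floor, alpha 0.05, fold change 1.5, e <= 0.1,
k >= 5) default to the values of the study design the package
reproduces and are configurable in `PipelineConfig`.
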