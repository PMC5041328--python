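# Methods

This note documents the models, conventions and numerical choices behind
`samsa`, in the order the pipeline runs.

## Annotation parsing and the export dialect

Annotation services emit per-read best-hit tables, but the exact column
layout of a tab-delimited export is not standardized.  Parsing is therefore
driven by an `AnnotationDialect`; the default layout is BLAST-tabular
flavoured — `read_id, match_id, percent_identity, alignment_length, evalue,
annotation_text` — because these exports are similarity-search derived, and
any real layout can be declared by passing a different `column_order`.
Two conventions matter downstream:

* **Tied best hits.**  A read whose best match score is tied between k
  references appears as k records sharing its `read_id` (the annotation
  service's own convention).  Parsing expands multi-entry annotation cells
  (`;`-separated) into one record per entry.
* **Malformed lines** are counted and reported rather than fatal by
  default; a `strict` flag turns them into hard errors for pipelines.
  Serialization refuses records whose text embeds a tab, newline or the
  multi-annotation delimiter, so write → parse is the identity on valid
  records.

One file carries one source database: the layout has no source column, so
mRNA (RefSeq/Subsystems) and rRNA (SILVA SSU) records are read and written
as separate files, matching how the downloads arrive.

rRNA partitioning is database-of-origin first (SILVA SSU ⇒ rRNA) with a
case-insensitive keyword fallback on the annotation text (defaults:
"ribosomal RNA", "16S", "23S", "5S"; user-extensible), since rRNA hits can
also surface in function annotations.

## Aggregation

Counting is a dictionary fold: each record contributes one unit
(`count_all`, the default, mirroring the service's tie handling) or 1/k of
a unit for a read with k tied records (`fractional`, which conserves read
counts instead of record counts).  Output tables are sorted by descending
count with a lexicographic tie-break, so identical inputs produce
byte-identical files.

Rank rollup sums organism counts at a chosen rank (phylum…genus) through a
user-supplied taxonomy map (exact, case-sensitive lookup); unmapped
organisms pool into `unclassified`, conserving totals.  Without a map only
genus is available, via the first whitespace token of the organism name
(binomial nomenclature); coarser ranks need lineage data the annotation
text does not carry.

Top-N display tables keep the N most abundant categories (default N = 30,
the usual stacked-bar convention for long-tailed communities) and either
pool the remainder into a reserved `Other` category (total conserved;
colliding input keys are escaped to `Other_`) or drop it.

## Depth sufficiency by subsampling

The question: how many annotated reads does a library need before relative
abundances are stable?  Procedure: draw random subsets of the full dataset
at fractions f (defaults 1–90% in the standard grid), `replicates` times
each (default 100); score every feature's accuracy against the full data,

    accuracy_f = 100 · (1 − |rel_s(f) − rel_full(f)| / rel_full(f)),

clamped to [0, 100] (the relative deviation of a rare feature can exceed
100%, and accuracies below zero carry no extra information); summarize
mean ± SD per (fraction, abundance class); report the smallest absolute
depth at which a class's mean accuracy clears a threshold (default 90%,
class `low` — the binding constraint in practice).

Key choices:

* **Subsampling on count tables, not reads.**  Drawing round(f·N) reads
  without replacement from the population implied by the counts is exactly
  a multivariate hypergeometric draw — distributionally identical to
  shuffling raw reads and orders of magnitude cheaper.  Tests verify the
  sampler against the exact hypergeometric pmf and against brute-force
  enumeration of all subsets of small parents.
* **Abundance classes** default to: high = the 5 most abundant features,
  medium = the top half of the sorted list minus high, low = the bottom
  tenth.  The stratification is configurable (`AbundanceClassSpec`) because
  percentile-style definitions are equally defensible; classes must be
  disjoint, and a table too small for that is rejected.
* **Aggregation within a class** is the unweighted mean over
  features × replicates, with the SD reported alongside.

The acceptance checks run this on a 2-million-annotation lognormal parent
with 2,000 features and 30 replicates per fraction — large enough that the
curve is smooth and strictly ordered (high ≥ medium ≥ low at every depth,
accuracy non-decreasing in depth, exactly 100 at the full dataset), and
small enough to run in seconds.

## Ribodepletion bias

Depletion kits remove rRNA unevenly across phyla.  With control and
depleted libraries rolled up to a rank (phylum by convention), the metric
per taxon t and sample pair i is

    d_i(t) = 100 · (1 − rel_depleted,i(t) / rel_control,i(t)),

averaged over pairs.  Relative abundances normalize each library, so the
metric is invariant to sequencing depth — and therefore *relative*: a
uniformly depleted community scores 0 everywhere, and taxa depleted less
than the community average score negative (apparent enrichment).  Taxa
absent from the control are not measurable and are reported as excluded;
taxa present in control but absent from the depleted library score 100.

The generator plants per-phylum retention factors r_p (each rRNA read of
phylum p survives with probability r_p, after which the library is
resampled to its original depth, mimicking fixed sequencing throughput).
Under this metric the expected depletion is 100·(1 − r_p/r̄) with r̄ the
abundance-weighted mean retention — not 100·(1 − r_p) — and the generator
emits that expectation as its truth so recovery tests do not re-derive it.

## mRNA vs rRNA concordance

Whether organism abundances estimated from mRNA agree with rRNA-based
estimates is scored as the Pearson correlation of relative abundances after
rollup to a rank, over the union of taxa (absent ⇒ 0, penalizing
detection dropout; an intersection mode exists for the complementary
question), optionally restricted to bacterial lineages via a flag in the
taxonomy map.  Fewer than three union taxa is an error (the correlation is
meaningless).  The statistic is symmetric and invariant to proportional
rescaling of either table.

## Paired-end vs single-read

The digital single-end simulation discards the reverse-read file and
truncates every forward read to its first `keep_length` bases (default
100 bp), qualities sliced in lockstep; shorter reads pass unchanged, so the
operation is idempotent.  The comparison of the two resulting abundance
tables reports totals, unique annotation counts, shared features, and
Pearson r on log₁₀(count + 1) over the feature union — the log transform
because annotation counts span orders of magnitude, the +1 because dropout
produces zeros.

## Differential abundance

A transparent NB workflow, deliberately simpler than a full DESeq2-class
implementation (no Cox–Reid adjusted likelihood, independent filtering, or
LFC shrinkage — each statistic here is reproducible by hand):

1. **Size factors** by median-of-ratios: s_j = median_f of
   K_fj / geomean_j(K_fj), over features with no zero in any sample.
2. **Dispersions** by method of moments on normalized counts:
   α̂_f = max(0, (s²_f − μ̄_f)/μ̄²_f) with s² the df-pooled within-group
   variance; a mean–dispersion trend α(μ) = a₀ + a₁/μ fitted by Huber
   robust regression on 1/μ̄; final dispersion = geometric combination
   raw^w · trend^(1−w) with w = 0.5 (equal faith in the per-feature
   estimate and the trend), floored at 1e−8.
3. **Wald test** on β_f = log₂(q_B/q_A): the group means are normalized
   sample means; when one is zero a pseudo-mean of 0.5 is added to both
   (flagged in the output) so the estimate is finite; SE from the NB Fisher
   information, Var(log q_g) = 1/Σ_j μ_gj/(1 + α μ_gj).  The statistic is
   referred to a t distribution with n − 2 degrees of freedom rather than
   the normal: with moment dispersions plugged in, the normal tail is
   mildly anticonservative at typical group sizes (measured ≈0.06 at
   α-level 0.05 with 8 samples per group), and the t reference restores
   calibration (≈0.04–0.05).
4. **BH step-up** over all tested features; output sorted by adjusted p,
   then raw p, then feature name.  All-zero features are reported (log2FC
   0, p = 1), never dropped.

Two-group designs only — the package's comparisons are all two-group.  A
test cross-checks signs, significant sets and fold-change estimates against
an independent NB reference implementation (pydeseq2) on a shared planted
fixture.

## Synthetic data

The generators emulate annotation exports, not sequencers: multinomial
reads over a community profile, per-taxon function catalogs with Dirichlet
within-taxon proportions, optional tied hits, rRNA routed to the SILVA SSU
source, planted per-phylum retention, NB count matrices with lognormal base
means (median 50, log-SD 1), lognormal sample size factors (log-SD 0.15)
and planted log₂ fold changes.  Community abundances default to lognormal
with σ = 1.5 — the long-tailed rank-abundance shape typical of gut
communities — with a Zipf-like power law as the alternative.  Every
generator is a pure function of its seed, and truths are returned in
machine-readable form.

What the generators do **not** model: sequence content and error,
annotation error and database incompleteness, within-taxon transcriptional
regulation, compositional coupling beyond the multinomial.  Passing tests
therefore demonstrate that the *procedures* are correct on data whose truth
is known — not that any given real library is deep enough, or that a real
depletion kit behaves multiplicatively.

## Degenerate inputs and tie-breaks

Empty record collections, zero-total tables, sub-3-taxon correlations,
single-sample groups and all-zero features are rejected or flagged
explicitly (see each function's docstring).  Every ordering in the package
(abundance sort, class assignment, DE output) breaks ties
lexicographically, so outputs are byte-stable across runs; no data file
contains a timestamp.

## Problem sizes

Defaults in the test-and-acceptance harness: 10,000-record aggregation
fixtures; a 2-million-annotation, 2,000-feature depth parent with 30
replicates per fraction; 100,000-read depletion pairs; 50,000-read
concordance draws; 2,000-feature null and 1,000-feature planted matrices at
8 samples per group.  These sizes make every distributional assertion
stable at 3–4 Monte-Carlo SDs while keeping a full run fast.
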