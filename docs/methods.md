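# Methods

This note documents the models, numerical choices and known limitations
of `binsplice`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Bin construction

Coordinates are 1-based inclusive internally (GTF convention); BED input
and output are converted at the boundary, and every emitted interval
file states its convention in its header.

Exons of all transcripts on a chromosome strand are flattened by a
sweep over their boundary events into the widest ranges where the set of
covering exon features is constant. CDS edges are added as extra
breakpoints, so a terminal exon splits into its coding part and its UTR
part even in single-isoform genes; without this, a one-isoform gene
would never expose a separate 3′ UTR bin. A fragment covered by exons of
several genes is emitted once per gene (flagged `gene_ambiguous`) unless
`genewise` flattening is requested, in which case genes are flattened
independently and may overlap each other.

Labels: a bin overlapping any CDS interval of its gene is `CDS`; a
CDS-free bin covered by at least one protein-coding transcript is `UTR`,
refined to `3UTR` when it lies strand-aware downstream of the last CDS
of one of its coding transcripts; bins with no protein-coding transcript
are `non-coding`. A transcript counts as protein-coding when it has CDS
records or carries a `protein_coding` biotype — GTF dialects differ in
which they provide. Transcripts coding by biotype only (no CDS anchor)
cannot distinguish 5′ from 3′, so their UTR bins keep the generic `UTR`
label (conservative).

### Poly(A) site segmentation

For each site (matched by chromosome and strand; unstranded annotations
are rejected because upstream/downstream would be undefined):

* a site inside an existing `UTR`/`3UTR` bin splits it at the site
  (a site on the bin's 3′ edge is a no-op — no zero-width bins); sites
  inside `CDS` or `non-coding` bins are ignored, since new UTRs are only
  defined from CDS/UTR context;
* otherwise the nearest strand-aware upstream `CDS`/`UTR`/`3UTR` bin
  boundary anchors a new `3UTR` bin from the boundary (exclusive) to the
  site (inclusive), inheriting the anchor's gene and transcripts. The
  candidate is discarded when it exceeds `max_utr_bin_size` (default
  15 000 bp, unlikely to be a real UTR), when a gene start lies between
  the boundary and the site (assignment would be ambiguous), or when it
  would overlap an existing bin of the same gene (preserves within-gene
  disjointness; this covers e.g. a non-coding transcript's exon sitting
  between the boundary and the site).

Sites are processed 5′→3′ per strand, so successive downstream sites
chain off previously created bins, producing one bin per inter-site
interval. New bins inherit all transcripts of the anchor bin; the
alternative (only transcripts whose annotated 3′ end precedes the site)
was rejected as it would frequently leave APA bins transcript-less.

## Counting

Every usable alignment (mapped, primary, non-supplementary, MAPQ ≥
threshold; duplicates kept by default since deduplication is a
protocol-level decision) adds 1 to every bin it overlaps by ≥ 1 bp.
Overlap is evaluated on aligned blocks (CIGAR M/=/X), so spliced reads
do not count bins inside their skipped introns. A paired-end fragment is
counted once per bin that either mate overlaps. Column sums therefore
legitimately exceed the number of reads (many bins are shorter than the
read length); the per-sample library size is the number of usable
fragments, not the column sum. Strand modes `forward`/`reverse` compare
the template strand (mate-2 flags flipped) with the bin strand.

## Pre-processing and per-bin models

The chain mirrors the standard count-modeling workflow; since no Python
implementation of these steps exists, they are implemented here from
the published algorithms and cross-checked against the R reference
implementations in the test suite.

* **Filtering**: keep bins whose CPM (against the median library size)
  reaches the CPM equivalent of `min_count` (default 10) in at least as
  many samples as the smallest design group (damped to
  `10 + (n−10)·0.7` for groups larger than 10), and whose total count
  reaches `min_total_count` (default 15).
* **TMM normalization**: reference sample is the one whose 75th
  percentile count fraction is closest to the mean of those; per sample,
  M and A values on double-positive bins are trimmed (30 % on M, 5 % on
  A) and combined with inverse-asymptotic-variance weights; factors are
  rescaled to geometric mean 1. An all-zero sample gets factor 1 with a
  warning.
* **Precision weights**: log2-CPM with a 0.5 count offset against
  effective library sizes + 1; square-root residual standard deviations
  from an unweighted fit are lowess-regressed (span 0.5, 3 robustness
  iterations) on average log2 count; weights are the inverse fourth
  power of the trend at each observation's fitted log2 count, clamped to
  the fitted range at the extremes (degenerate all-equal inputs fall
  back to flat weights).
* **Weighted least squares** per bin gives β̂, the unscaled standard
  deviation u (tested diagonal of (XᵀVX)⁻¹), the residual variance and
  its degrees of freedom. The two-group design is intercept + condition
  indicator; the tested coefficient is the condition log2 fold change.
* **Empirical-Bayes squeezing**: a scaled-F/inverse-chi-square prior is
  moment-matched on the log scale (digamma/trigamma correction; Newton
  inversion of the trigamma function). When the observed spread does not
  exceed sampling noise the prior degenerates (d₀ = ∞) and posteriors
  equal the arithmetic-mean prior variance, matching the reference
  implementation's convention. The legacy path averages bin variances
  within genes (df summed) and squeezes the gene values; the improved
  path squeezes bin variances directly.

Moderated degrees of freedom for the t reference distribution are
residual df + prior df, capped at the total residual df; this standard
moderation choice is not dictated by the statistic itself and is
recorded in the run log.

## The two statistics

See the README for the formulas. Design notes:

* Genes need ≥ 2 tested bins; single-bin genes are reported with NA
  statistics rather than silently dropped. Bins with u = 0 are excluded
  with a warning.
* BH adjustment runs over tested bins only; gene-level Simes p-values
  get their own BH pass.
* UTR restriction sets non-UTR bin p-values to 1 **for aggregation
  only** (bin-level Ĉ values are kept for display). Since the Simes
  combination is monotone in every p-value, masking can only raise a
  gene's p — never manufacture significance.
* Gene effect scores use significance weights ω = −log10 p capped at 10
  (the cap prevents one extreme bin from dominating); the UTR-mode score
  additionally weights by bin width in kb and keeps the coefficient
  sign. The exact functional form of "weighted by size and
  significance" is a documented, configurable choice — only the ranking
  it induces is relied on.

### Calibration trade-off

The legacy statistic's rescaling D̂ₖ = Ĉₖ√(1 − wₖ/Σw) is exactly the
correction for the variance contributed by the leave-one-out average B̂ₖ
under the constant-variance model, and the legacy test is accordingly
well calibrated under the null (verified in the test suite). The
improved statistic deliberately drops this rescaling and uses Ĉₖ
directly; the gain in effect-size interpretability and power comes at
the price of mild anticonservativeness for genes with few bins (the
null variance of tₖ is inflated by roughly 1 + 1/(n_bins − 1)). The
test suite measures this honestly: with 4–8 bins per gene the improved
statistic rejects ~8–9 % of null bins at α = 0.05 where the legacy one
rejects ~5–6 %. Users who need strict type-I control at the bin level
should prefer the legacy method or gene-level FDR.

## The synthetic benchmark

`simulate_utr_counts` emulates a differential-UTR read simulation at
the count level — sufficient to exercise the statistics, while read-
level fixtures for the counter are generated separately as small SAM
texts (`make_read_fixture`). Per gene: 4–8 bins partitioned into a CDS
core, a proximal 3′ UTR segment and up to three distal segments; a
short and a long isoform differ by inclusion of the first k distal
segments (k ∈ {1,2,3}, emulating extension to the next, second-next or
third-next downstream poly(A) site). Defaults: 500 genes, 100 with a
usage change (opposite fold changes f and 1/f, f ~ U(1.3, 5), random
direction), 30 of those plus 30 unchanged genes also get a whole-gene
fold change from the same range; two conditions × 3 replicates;
negative-binomial counts with per-bin dispersion lognormal around 0.1
(log-sd 0.5) and lognormal bin widths (median ≈ 300 bp). The dispersion
and width spread are deliberate realism choices: with a single shared
dispersion the per-bin variance modeling of the improved statistic is a
no-op by construction, which is not the data regime the method
addresses. Gene abundances are lognormal (log-mean 5, log-sd 1), and
isoform shares uniform in [0.3, 0.7].

What the generator does **not** emulate: read-level error models,
fragment GC/positional bias, mappability, overlapping genes and
ambiguous assignment, or correlation between dispersion and mean beyond
the voom trend. Passing benchmarks here therefore demonstrates correct
statistical behaviour under a clean generative model, not end-to-end
performance on real libraries.

The fixed benchmark (seed 0, the generator default) is used for the
power comparison: gene-level AUROC of the improved statistic must reach
0.80 and be at least that of the legacy one. Problem sizes throughout
the suite (500-gene benchmark, 300-gene null) are chosen so the entire
test suite completes in seconds while keeping ≥ 1000 null p-values per
calibration estimate.

## Determinism and degenerate inputs

Everything downstream of the simulator is seed-free and deterministic;
the simulator is fully determined by its config (single `numpy`
Generator). Output tables are written with a fixed float format under a
commented parameter header, so re-running a config overwrites outputs
byte-identically. Degenerate cases: zero-variance bins fit exactly with
σ̂² = 0; identical variances squeeze to a point prior; genes whose bins
are all masked aggregate to p = 1; an APA site coinciding with a bin
edge is a no-op; all-zero samples get normalization factor 1.
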