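# Methods

## The signal model

Palindrome enrichment concentrates sequencing reads at fold-back junction
loci. After counting reads in 1-kb non-overlapping bins and normalizing to
counts per million mapped reads (cpm), three populations of bins coexist in
a GAPF library:

* **background** — the vast majority of bins, near zero coverage (most
  non-palindromic DNA is nuclease-digested);
* **recurrent artifacts** — bins enriched in tumor *and* normal libraries
  alike (germline inverted repeats, GC-rich regions that resist
  denaturation, repetitive elements); they carry no tumor information and
  are removed by the blocklist;
* **palindromic signal** — bins over true fold-back junctions. In normal
  DNA these are scattered genome-wide; in tumor DNA,
  breakage–fusion–bridge amplification concentrates them on the amplified
  chromosome(s).

The classifier exploits only the spatial statistic of that third
population: with the top K = 1000 bins by cpm, a sample's score is the
maximum per-chromosome HCB count, and a sample is called positive when the
score reaches a global threshold on any one chromosome.

## Coverage counting

Reads are counted into half-open, 0-based bins tiled from position 0; the
final bin of a chromosome may be short and is counted like any other (no
bin-level length normalization — lengths enter only at the cytoband
level). A read increments every bin it overlaps by ≥ 1 bp, matching
`bedtools coverage -counts`; mates are counted independently; unmapped,
secondary and supplementary records are excluded. The uniqueness filter
passes MAPQ ≥ 40 (`samtools view -q 40` semantics). No duplicate
marking/removal is performed. cpm is the single linear rescale
`raw · 1e6 / total_mapped_reads`.

## QC scores

Control germline inverted repeats are amplified by the enrichment but are
multi-mapping, so the MAPQ filter should remove them. The amplification
score is the mean over control regions of each region's mean *unfiltered*
(MAPQ ≥ 0) bin cpm; the depletion score is the same two-level average on
the MAPQ ≥ 40 coverage. A library passes iff amplification > 1.0 and
depletion < 0.075, both strict. The package ships no fixed control
coordinate set — regions are supplied as a 4-column BED; the simulator
plants multi-mapping repeats to exercise the scores.

## Blocklist

"Recurrently enriched in both arms" is operationalized as: cpm >
`enrich_cutoff` (default 5, the empirical low/high coverage divide) in ≥
`min_fraction` (default 0.75) of tumor samples **and** of normal samples.
Both parameters are recorded in the blocklist's provenance sidecar, and
an externally curated blocklist BED is accepted verbatim. Application is
a pure restriction of the coverage track (idempotent; retained values
unchanged), so retained-bin accounting is exactly
`total − |blocklist|`.

## HCB ranking and profiles

Bins are sorted by cpm descending with a fully deterministic tie rule
(chromosome order as given, then start ascending), making the selected
top-K set and all downstream outputs bit-exact across runs. Profiles
default to chr1–22 + chrX + chrY; the ML feature vector uses chr1–22 +
chrX (23 features). Cytoband assignment uses the bin's start position —
bins are 1 kb against Mb-scale bands, so boundary effects are negligible.
Cytoband coverage is (Σ bin cpm in band) / band length in bp. Bands on
unlocalized/unplaced sequences (names containing `_`) are dropped at
ingestion.

## Threshold model

The ROC sweeps all distinct observed scores plus an all-negative sentinel
(max + 1); positive calls use score ≥ threshold (a `strict_gt` flag flips
the boundary). AUC is trapezoidal over sensitivity vs (1 − specificity)
with vertical segments traversed upward, which makes it exactly the
Mann–Whitney pair statistic with ties counted ½ — a property the test
suite asserts on random inputs. Youden ties break toward the smallest
(most sensitive) threshold.

Cross-validation refits the Youden threshold on each training split
(proper CV) and additionally reports the whole-cohort threshold, which is
the single-number operating point a user would deploy. Partitions come
from scikit-learn's stratified k-fold after seeded shuffling; the same
seed always yields the same partition. Summary dispersion is reported
both pooled over all fold×seed values and at seed level, since either
aggregation is defensible.

## ML comparison

The comparison layer deliberately avoids AutoML: fixed-default
scikit-learn models (GaussianNB, RandomForest with 200 trees, gradient
boosting; xgboost as an optional plugin behind the same name-keyed
factory) under the same seeded 3-fold protocol. Permutation importance is
the drop in held-out AUC when one feature column is shuffled (repeats
seeded and averaged). Composite importance floors negative raw scores at
zero, normalizes by each algorithm's maximum positive score to [0, 1],
weights by that algorithm's median AUC and sums across algorithms —
accurate models count more. Rank tests on chrX counts are delegated to
standard statistics routines; the package only extracts the per-group
count lists.

## Read-pair scanning

Orientation is derived solely from the two mates' strands: FF / RR when
equal (the fold-back signature), else FR / RF by the leftmost mate's
strand; inter-chromosomal pairs are excluded as "other". FF/RR pairs with
both mates at MAPQ ≥ 40 are merged greedily in coordinate order whenever
both mate positions fall within 1 kb (defaults: `min_support` 3,
`merge_distance` 1000 bp — configurable, chosen as typical discordant-pair
clustering values). Insert-size partitioning routes exactly-200-bp inserts
to the long stream (`< 200` short, `≥ 200` long), with a flag to flip the
boundary; unpaired records go to neither stream and are counted.

## Simulator

Counts are negative-binomial in a mean/dispersion parameterization
(variance = μ + μ²/r) — the simplest overdispersed count model, since the
data model here is calibrated only to coverage summaries, not to a
mechanistic read model. Defaults encode the study conditions: 39
tumor/normal pairs; background mean 0.31 cpm; ~2.4% shared artifact bins
at 50 cpm; 1,200 dispersed high bins per sample at ~12 cpm spread in
proportion to chromosome length; one planted contiguous cluster of
100–300 bins per tumor at 20–65.5 cpm on a random autosome (65.5 cpm is
the undiluted peak anchor). The toy genome is 24 pseudo-chromosomes of
5 Mb (120,000 bins), chosen so full cohort runs finish in seconds while
leaving the top-1000 selection a < 1% tail of the bin population. cpm is
defined against a nominal library depth of 10⁷ mapped reads; the binned
counts sum to far less, read as the bulk of fragments being
nuclease-digested or off-manifest.

Dilution series scale the planted peak's expected cpm linearly with tumor
fraction before noise — the simplest mechanism consistent with a monotone
exponential-looking decay over the dilution ladder; the background is
unchanged. Junction libraries emit FR pairs plus a configurable fraction
of junction-spanning pairs whose far mate is reflected across the
junction position (FF approaching from the left arm, RR from the right).

What the simulator does **not** emulate: GC and mappability biases,
fragment-length structure, real blocklist composition, germline
palindrome polymorphism, chromosome-length heterogeneity, or base-level
sequence (no FASTQ). Passing tests therefore demonstrate the pipeline's
correctness and the statistical identifiability of clustered-vs-dispersed
HCB signal under the stated noise model — not performance on real
libraries.

## Numerical and design choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical (spec, seed) pairs give
  byte-identical outputs.
* Coverage histogram ranges are half-open `[e_i, e_{i+1})`, including the
  top edge exactly.
* The exponential dilution fit is ordinary least squares of ln y on x
  (not nonlinear least squares); two-point fits are exact and flagged
  degenerate; nonpositive y is rejected.
* Degenerate CV folds (missing a class) are excluded from aggregation
  with a warning rather than poisoning the means.
* Reads on chromosomes absent from the bin manifest are skipped and
  counted, not fatal — mixed-manifest BAMs are common in practice.
* Total bin counts are manifest-dependent (they change with the contig
  set of the chrom.sizes provided); the package treats them as derived
  accounting, not constants.

## Problem sizes

Default test and acceptance runs use the 120,000-bin toy genome, 39+39
sample cohorts, 3-fold × 3-seed CV, 10-seed dilution recovery and
300-pair junction libraries; the full suite and the acceptance script each
complete in well under a minute on a single CPU.
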