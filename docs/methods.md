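# Methods

This note documents the model behind tescout's caller, the parameters that
matter, the simulator's scope, and the numerical choices made where the
design was genuinely open.

## Detection model

The caller assumes a paired-end library with an approximately stationary
fragment-length distribution, a coordinate-sorted indexed BAM, and a TE
annotation whose features carry unique `Name=FAMILY_x` tags (family = name
with the trailing `_digits` removed). Fragment length is taken as the outer
distance (|TLEN| of proper pairs); mean and standard deviation are estimated
over the first 1,000,000 proper pairs (population SD — at that n the
sample/population distinction is far below measurement noise, and it makes
small-fixture tests exactly predictable). Fewer than 100 proper pairs is
treated as an unusable library.

A pair is a discordant candidate when it is not proper-pair-flagged and its
reads map to different chromosomes or at a mapping distance greater than
2×fragment_mean. "Mapping distance" is the difference between the two reads'
leftmost coordinates: unlike TLEN it is well defined regardless of overlap
and aligner sign conventions. A read is *repetitively mapped* when its mapq
is 0 or it carries an alternative-hit (XA-style) tag; the anchor of a pair
must be non-repetitive, have mapq ≥ `mapq_min` (default 15 — below that,
empirically, reads occur almost exclusively in false-positive calls), and
overlap no annotated TE, while the mate must overlap ≥1 bp of an annotated
TE at its primary or any alternative placement. The mapping-quality filter
deliberately applies to the anchor only: aligners give repetitive reads the
lowest score, and the TE mate is *expected* to be repetitive.

Each anchor predicts an insertion in the interval reaching
`fragment_mean + s*fragment_sd` downstream from its start (strandwise); the
near bound is the anchor's inner edge, since the insertion must lie beyond
the anchor read itself. `s` (default 2) controls the tolerance for fragment
length jitter; 2 matches the `2*sdev` term in the interval-length cutoff, and
the interval width `fragment_mean + s*sdev − read_len` must exceed the spread
of anchor start positions (≈ the same quantity) for a site's anchors to form
one clique — smaller `s` fragments true clusters.

### Clustering

Same-strand anchors are clustered into maximal mutually-overlapping interval
sets. Because 1-D intervals have the Helly property, such sets are exactly
the maximal cliques of the interval-overlap graph and are enumerable by a
single left-to-right sweep (the active set is emitted whenever it is about to
shrink after having grown); the sweep is verified in the tests against
brute-force clique enumeration. Two clusters are *overlapping* — and both
discarded, keeping only isolated clusters — when they share a member or
their intersection intervals overlap; distinct maximal cliques can never
overlap in their intersections (a shared point would merge them), so the
operative criterion is member sharing. Each retained anchor therefore
belongs to exactly one cluster.

Forward and reverse clusters pair when their intervals overlap, with
endpoints treated as **closed**: the innermost forward anchor typically ends
exactly at the junction (soft-clipped there) and the innermost reverse
anchor starts there, so the two predicted intervals abut at precisely the
insertion coordinate — under strict half-open overlap essentially every true
insertion would be rejected. A cluster overlapping several opposite-strand
clusters is ambiguous; all clusters involved are dropped (specificity first).
The insertion-site interval runs from the greatest forward anchor start to
the smallest reverse anchor end; if those cross (stacked reads) the interval
collapses to their midpoint with length 0.

Work is partitioned into genomic bins (default 50 Mb). Each bin is processed
with an overlap margin of 4×(fragment_mean + s×sdev) and owns only the calls
whose insertion-site midpoint falls inside it, so the call set is provably
independent of the bin size (tested) — binning is an execution detail, not a
model parameter. Bins are processed serially in genomic order; a process
count is accepted for interface compatibility but never changes results.

### Breakpoint, zygosity, filters

Soft-clip boundaries of reads overlapping the insertion interval are
collected when the clip is ≥5 bp (`min_clip`; shorter clips are mostly
adapter/quality artefacts), grouped greedily left-to-right within ±3 bp of
each group's first member, and the modal position of the best-supported
group is the breakpoint (ties: leftmost group; modal ties: leftmost
position). Core reads are proper-paired reads covering the breakpoint by ≥5
nt on each side and *not* clipped at it — a read clipped at the breakpoint
is insertion evidence even if proper-paired, so the two counts are disjoint.
Zygosity = clipped/(clipped+core); it is absent (not 0) when no evidence
exists, in which case the call also cannot pass the clipped-support filter.

Filter cutoffs are generated from the library statistics and coverage (see
README for the four formulas); all comparisons are strict, the cluster-size
and span bounds apply to each strand's cluster separately, and the generated
values are written into the run's config file so re-filtering is
reproducible. TE consistency (forward and reverse mates naming a common
element) is reported but not enforced by default — it is a diagnostic, not a
printed cutoff. Coverage is total aligned bases over total reference length
(rounded to one decimal), overridable by a user flag.

### Somatic classification

Filtered tumor calls are subtracted against the *raw* normal calls (padded
200 bp symmetric overlap — subtraction against the unfiltered set avoids
re-introducing germline calls the normal filter happened to drop). For each
tumor-unique call, a 200 bp window around the locus (breakpoint if present,
else interval midpoint) in the normal BAM is examined: a discordant-read
fraction ≥2 % marks a germline insertion missed in the normal sample; mean
window coverage <8X marks the locus indeterminate; the rest are somatic. The
window defaults to 200 bp and is a parameter (the source material is
internally inconsistent between 200 and 400 bp; the Methods value wins).

## Simulator

`tescout.sim` emulates the study conditions end to end:

* **Genome** — uniform-random background with planted TE families: each
  family a random consensus (500–3000 bp), copies diverging from it at 2 %
  per base, ≥2 kb apart. Copies of one family are mutually similar, so a new
  insertion's reads map to other family members — the premise the caller
  relies on. Copy orientation is annotated but copies are not
  reverse-complemented (orientation is irrelevant to the mapping geometry the
  caller sees).
* **Insertions** — donors drawn uniformly from annotated copies ≥200 bp and
  *copied* (not cut) to random positions ≥100 bp from annotated TEs, ≥1 kb
  from sequence ends and ≥2 kb from each other. The separation floor exists
  because ~300 insertions in 3 Mb would otherwise collide within a fragment
  length far more often than the full-genome designs being emulated, and
  colliding clusters are (correctly) dropped as ambiguous. The normal design
  uses two alleles (homozygous in both, heterozygous in one); the tumor
  design uses four allele copies 2×A1 : A2 : A3 with the low-cell-fraction
  set on A3 only, giving true allele fractions 1.0 / 0.5 / 0.25.
* **Reads** — fragments N(450, 40) bp, 100 bp pairs, drawn per allele in
  proportion to copy number; substitution errors at 0.1 % per base (typical
  short-read scale). Reads are rendered directly as alignments via the exact
  allele→reference liftover: fully-reference reads become proper pairs at
  their true positions (proper = FR orientation within mean±4 SD); mates
  fully inside an inserted TE are placed at the donor copy with XA entries
  for the other family copies (mapq 0 when copies are identical, i.e. zero
  divergence, else 37); junction-crossing reads are soft-clipped at the
  insertion point with the longer segment mapped. Output is a
  coordinate-sorted, indexed BAM with a canonical header, byte-identical for
  identical seeds; FASTQ export is available for running a real aligner.

What the emulation deliberately does **not** model: mapping errors (placement
comes from the liftover, so substitution errors never mislocate a read),
local coverage and GC bias, indel errors, target-site duplications (an
optional consideration for validation work, not detection), and nested
insertions inside annotated TEs (excluded by design — the caller only
predicts insertions in non-repetitive sequence). Benchmark results are
therefore a best case for alignment-related errors: PPV ≈ 100 % on clean
simulations says the clustering/filtering logic itself produces no
artefacts, not that real data will be artefact-free. Conversely,
evidence-counting statistics (zygosity distributions, Poisson thinning of
clipped support at low per-allele coverage) are faithfully reproduced.

### Scoring

A call matches a truth record when its locus (breakpoint, else interval
midpoint) lies within 20 bp; matching is one-to-one, greedy by distance.
Zygosity is classified to the nearest truth class present in the truth set,
with the homozygous boundary at 0.75 and ties going to the larger fraction
(the boundary mirrors how a hom/het decision would be made; the nearest-class
rule extends it to the 0.25 tumor class).

## Benchmark problem sizes and expected behaviour

The shipped benchmark (tests and `scripts/acceptance.py`) uses a 3 Mb genome,
3 families × 10 copies, 75 hom + 75 het + 73 LCF insertions — a deliberate
desk-scale rendition of the full-genome designs, chosen so the whole
benchmark completes in minutes on one CPU while keeping ≥70 truth records
per allele-fraction class. At these sizes: filtered PPV is 100 % at
10X/20X/40X, hom/het classification at 40X is ≈99 %, recalled homozygous
insertions read zygosity exactly 1 (no reference allele exists, so core
reads are structurally impossible), het and LCF mean allele fractions land
within 3 binomial SE of 0.5 and 0.25, and every recalled breakpoint is exact
to the base.

One quantity is systematically below its real-data counterpart: LCF
detection at 20X (≈74–84 % across seeds vs ≈89 % reported on real
aligner/error-model reads). At 20X the carrier allele contributes 5X, the
number of clipped junction reads is Poisson with mean ≈4–4.6, and the strict
`clipped_support > 2` cutoff then removes ≈16–23 % of the loci (raw
detection is 100 %). This is an honest property of the evidence model at
that depth, not a parameter to adjust.

## Known limitations

* Split-read (supplementary-alignment) evidence is not used.
* Insertions inside annotated TEs are not called.
* No VCF output; calls are GFF3 + TSV.
* The somatic module reports zygosity but does not deconvolve cancer-cell
  fractions, and handles pairs only (no trios).
* The simulator's aligner emulation cannot surface reference-bias or
  mappability artefacts; for those, export FASTQ and run a real aligner.
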