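# Methods

## Problem setting

Polyadenylation signals (PAS; canonically the hexamer AATAAA) inside
introns are normally silenced by the splicing machinery — recognition of
the 5' splice site by U1 snRNP suppresses nearby cleavage/polyadenylation
("telescripting").  Where an intronic PAS *is* used, the transcript is
truncated inside the intron, producing an alternative 3'-exon isoform.
`intronpas` analyses an annotated genome along four axes: how common
PAS-like hexamers are in introns, how often genes are nested inside other
genes' introns (where a nested gene's PAS sits inside a host intron), which
genes are annotated with an isoform terminating inside an intron of a
sibling isoform, and — given RNA-seq alignments — how strongly each of the
two isoforms is expressed per sample.

## Coordinate model

All internal coordinates are 0-based, half-open (`length = end − start`);
GFF3 I/O converts from the on-disk 1-based inclusive convention at the
file boundary.  Introns are derived per transcript as the gaps between
consecutive exons, then deduplicated genome-wide by
(chromosome, start, end, strand).  Both the deduplicated count and a
per-transcript count are available, since published intron totals differ
in which convention they use.  Strand `.` is accepted on input but such
genes are excluded from strand-relationship statistics.

## PAS scanning

Intron sequences are scanned on the transcript's sense strand (PAS
function is strand-specific; minus-strand introns are reverse-complemented
before scanning).  Scoring is a weighted hexamer lookup: AATAAA at 1.0,
ATTAAA at 0.9, and ten common single-base variants (AGTAAA, TATAAA,
CATAAA, GATAAA, AATATA, AATACA, AATAGA, AATGAA, ACTAAA, AAGAAA) at 0.5,
with a default reporting threshold of 0.9 — so by default only the two
strong variants call a site.  The table is deliberately transparent and
fully user-replaceable (two-column TSV); this is a documented scoring
scheme of this package, not an emulation of any trained PAS predictor, and
absolute "PAS present" fractions are therefore tool-dependent and not
comparable across scoring schemes.  Introns shorter than 120 bp (default,
configurable) are reported as `too_short` and never scanned; the three
categories (`present`, `not_found`, `too_short`) always partition the
intron set.  Windows containing N never match.  Raising the threshold can
only shrink the `present` set (monotonicity).

## Nested genes

A gene is nested when its span lies strictly inside an intron of another
gene: start strictly greater than the intron start and end strictly
smaller than the intron end.  Boundary-touching genes are excluded.
Containment is tested on gene spans against the deduplicated union of the
host's introns over all isoforms; a gene contained in introns of several
hosts yields one pair per host, and within one host a nested gene counts
once (the smallest containing intron is reported).  The search uses one
interval tree of gene spans per chromosome; an all-pairs brute-force
implementation with identical semantics lives in the test suite and the
two are asserted equal on 100 seeded annotations.  Summaries report
distinct hosts, distinct nested genes, the number of nested genes
co-directional with their host, a host-side grouping (all nested genes on
the same strand / all opposite / mixed), and the affected-gene fraction
(hosts + nested over all genes).

## Intron-terminated isoform catalogue

A gene enters the catalogue when an isoform's 3' end lies strictly
between the donor and acceptor of one specific intron of a sibling
isoform, and the terminating isoform's last exon starts strictly upstream
(transcription direction) of that donor.  All comparisons mirror on the
minus strand.  Two filters follow:

1. **overlap exclusion** — a candidate gene whose span overlaps any other
   gene's span (either strand by default; same-strand-only available) is
   dropped, because reads in the overlap cannot be attributed;
2. **two-form selection** — only genes with exactly two annotated
   transcripts forming the spliced/terminated pattern are kept, so the
   two-isoform read-density model below applies.

The funnel counts (candidates → overlap-excluded → two-form retained) are
reported at each stage.  Candidate counting is per gene; the per-event
count (gene, isoform pair) is reported alongside.

## Read-density quantification

Read density is mean per-base aligned coverage over a region, CIGAR-aware:
M/=/X add coverage, N and D consume reference without coverage, so
junction reads contribute nothing to the intron interior.  Multi-mapped
reads count once per alignment record; a read-count density mode (records
overlapping the region divided by region length) is available for
comparison with tools that count reads rather than bases.

For a two-form gene with termination point T inside intron (donor D,
acceptor A):

* spliced level `S` = mean depth over the spliced isoform's 3'-exon;
* intronic level `I` = max(0, depth(D→T) − depth(T→A)).  The subtracted
  acceptor-side term estimates the uniform unspliced pre-mRNA background
  covering the whole intron, which would otherwise masquerade as the
  terminated isoform.  The raw (unclamped) difference is also reported,
  since a strongly negative value flags a model violation;
* proportion `p = I / (I + S)`, flagged undefined (not 0/0) when both
  levels are zero.  Whenever defined, `p ∈ [0, 1]`, and duplicating every
  read leaves `p` unchanged.

No cross-sample normalisation is applied: levels are compared in raw
read-density units, and the proportion is scale-free within a sample.

## Expression grouping and heat map

Genes quantified across samples are labelled: `no_intronic_form` when the
intronic level never exceeds the noise floor; `no_splicing` when the
spliced level never does; `switching` when both isoforms exceed the floor
somewhere and the proportion range across samples reaches the switch
delta; `misannotated` only from an explicit blacklist (annotation errors
are a manual call); otherwise `unclassified`.  The noise floor defaults to
1.0 read-density unit and the switch delta to 0.2 — these are free
parameters of this package (no principled universal values exist; the
baseline-noise notion is inherently qualitative), are echoed in all
outputs, and should be tuned to library depth.  Precedence of the rules
makes the labels a partition, and raising the noise floor never moves a
gene out of `no_intronic_form`.

The heat-map matrix has three rows per gene — spliced level, intronic
level, proportion — across samples, rendered with separate colour scales
for levels (sequential) and proportions (diverging, fixed to [0, 1]).

## Synthetic data generator

The generator is first-class, tested code and defines the conditions under
which the pipeline is validated.

* **Architecture.**  `n_genes` primary loci on one chromosome; a fraction
  (default 0.10) host a nested gene inside a dedicated long intron
  (margin 40 bp on each side, so containment is strict), with 44% of
  nested genes co-directional with their host — the share observed among
  annotated nested genes genome-wide; a fraction (default 0.20) carry the
  two-form spliced/terminated isoform pair, of which 20% get an
  overlapping neighbor gene (to exercise the overlap filter) and 20% a
  third isoform (to exercise two-form selection).  All counts are
  deterministic rounded fractions, not samples.  Nested and neighbor genes
  are extra loci on top of `n_genes`.
* **Introns.**  Lengths are a short/long mixture: 55% short (60–119 bp,
  below the scannable minimum — the genome-wide share of sub-120-bp
  introns) and the rest long (300–900 bp).
* **Sequence.**  Random uniform nucleotides; every scannable intron is
  scrubbed of all twelve table hexamers, then exactly
  `round(0.40 × n_long)` long introns (seeded permutation) receive one
  planted sense-strand AATAAA.  A self-check rescans every long intron and
  verifies the planted truth, so the `present` fraction equals the planted
  fraction exactly at the default table and threshold (scrubbing is
  against the default table; exactness is not guaranteed for custom
  tables).
* **Reads.**  Per sample, each gene's reads are drawn uniformly along the
  expressed isoform (Poisson count at the configured depth, default 50×,
  read length 75), truncated at the transcript 3' end so coverage is flat
  except a ramp over the first read-length bases at the 5' end — the
  quantified regions all sit away from that ramp.  Spliced reads crossing
  the junction carry N CIGAR operations.  Candidate genes mix the two
  isoforms at the sample's true θ; a uniform unspliced pre-mRNA background
  (default 0.25×) covers each whole locus, giving the acceptor-side
  subtraction something real to remove.  θ profiles emulate the planted
  expression groups: 0 everywhere (`no_intronic_form`), 1 everywhere
  (`no_splicing`), or a 0.1→0.8 ramp across the sample panel
  (`switching`); an explicit per-sample θ override supports dose-response
  experiments.  The default sample panel is 4 cell lines plus 30
  developmental stages.
* **Determinism.**  All randomness flows from (config, seed) through
  per-stage child generators; identical inputs give byte-identical GFF,
  FASTA, SAM and truth JSON.
* **Not modelled** (hence not demonstrated by passing tests): sequence
  errors, fragment-length and positional coverage biases, expression-level
  dispersion across genes, multi-chromosome genomes, overlapping
  transcription beyond the planted cases, and reads from unannotated
  isoforms.  Real-data behaviour on those axes is untested.

## Validation experiments and problem sizes

The acceptance checks run at sizes chosen to exercise every code path while
remaining quick on one CPU: oracle equivalence on 100 annotations of ~30
primary genes; θ recovery on a 60-gene genome over θ ∈ {0, 0.25, 0.5,
0.75, 1} at 50× (mean absolute error of the mean recovered proportion per
θ must stay below 0.05 — observed ≈ 0.01); partition invariants on every
fixture; strict-boundary unit cases; and depth conservation against a
per-base pileup oracle.  `scripts/acceptance.py` re-runs the same three
experiment families (a 200-gene structural cohort, the θ grid, and an
80-gene four-sample grouping cohort) from a single command-line seed.

## Known limitations

* The hexamer table is a fixed lexicon; it has no positional or
  context weighting, so genome-wide `present` fractions are not
  comparable with trained PAS predictors.
* The overlap filter drops whole genes on any-strand span overlap — the
  strictest reading; annotations rich in overlapping genes lose many
  candidates (the same-strand-only switch relaxes this).
* The intronic-level estimator assumes the unspliced background is
  uniform across the intron; 3'-biased protocols violate this.
* Group thresholds are global, not per-library; heterogeneous depths
  across a sample panel warrant per-sample normalisation upstream, which
  this package intentionally does not perform.
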