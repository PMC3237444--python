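# Methods

`srnamir` re-implements, as a tested and reusable pipeline, the classic
plant small-RNA analysis workflow: two single-end sRNA-seq libraries from a
before/after treatment contrast are collapsed into unique tags, filtered
through a structural-ncRNA annotation cascade, searched for miRNA hairpins
on genomic references, quantified as per-million normalized counts with
signed fold changes, and scanned against a transcript set for miRNA target
sites.  This note records the models, defaults and design choices, and what
the synthetic test bed does and does not demonstrate.

## Read cleaning and tag collapsing

Reads are accepted only when they carry a recognizable 3' adapter
(default: the Illumina TruSeq small-RNA 3' adapter, `TGGAATTCTCGGGTGCCAAGG`;
configurable because real studies rarely publish theirs).  The adapter is
anchored at the leftmost read offset with at least `min_overlap = 6` aligned
bases and a mismatch rate at most 0.1; the insert is the prefix before that
offset.  Adapterless reads are discarded rather than passed through, because
without the adapter the 3' boundary of the insert is unknown.  Inserts are
kept when 18-30 nt with no `N` (tags must be exact-matchable), then
collapsed to unique tags with per-library redundant counts.  Collapsing
conserves redundant totals exactly and is idempotent; both properties are
asserted on every pipeline run.  Quality filtering is assumed to have
happened upstream in the base-calling pipeline; an optional minimum mean
phred cutoff exists but defaults to off.

## Annotation cascade

Tags matching rRNA, tRNA, snRNA, snoRNA or repeat references are removed
from discovery.  Matching is exact full-length substring containment of the
tag in a reference sequence, on either strand.  Exact matching was a
deliberate choice: it is conservative, independent of aligner heuristics,
and checkable against a naive string-scan oracle.  The cascade is a fixed
priority (rRNA > tRNA > snRNA > snoRNA > repeat > unannotated) so that the
class assignment is a deterministic partition: per-class unique and
redundant counts always sum to the library totals, which the summary table
asserts at run time.  Redundant/unique ratios are reported at two decimals
with half-up rounding, matching how such tables are conventionally printed.

The *clean* library size -- the normalization basis for expression -- is
the redundant total minus the four structural-RNA classes (repeats and
miRNAs stay in), computed from the same summary.

## Secondary-structure folding

Hairpin validation needs a deterministic, dependency-free minimum-free-
energy folder, so the package carries a compact Zuker-style dynamic program
over pseudoknot-free structures:

- sequence-dependent stacking energies for adjacent canonical pairs
  (Watson-Crick + G:U), an approximate Turner-style 6x6 table;
- size-dependent hairpin-loop (min 3 unpaired) and interior/bulge-loop
  penalties with Jacobson-Stockmayer log extrapolation for large loops;
- an affine multiloop cost (closing 3.4 kcal/mol, 0.4 per branch, free
  unpaired bases);
- no dangles, no coaxial stacking, no terminal-AU penalties.

The open chain scores 0, so the MFE is never positive.  Interior loops are
capped at 30 unpaired bases in the search (standard practice; irrelevant at
precursor scale).  The model energy of *any* structure is computable by
`folding.structure_energy`, which makes the DP testable: on hundreds of
random sequences short enough to enumerate every structure exhaustively,
the DP optimum equals the enumeration optimum exactly.  The fill runs under
numba when available (it is, in the supported environment) with a
pure-Python fallback.  This folder is a triage tool for hairpin screening,
not a replacement for a full thermodynamic package: absolute energies are
approximate, and the reported MFE statistics should be read comparatively.

## Hairpin discovery and miRNA criteria

Candidate tags are the unannotated tags with at least `min_candidate_count
= 5` total redundant reads.  The count threshold is a pragmatic addition:
single-copy degradation fragments are overwhelmingly noise, and folding
every one of them would dominate runtime without changing the outcome.

Candidates are anchored on the genomic references by exact match (both
strands; a perfect match is required, as in the workflow this package
models).  Around each locus two precursor windows are extracted (long
flank, default 150 nt, upstream or downstream, with 20 nt on the other
side), reverse complemented for minus-strand loci so mature offsets always
live on the precursor sense strand.  Each window is folded and screened
against community-standard plant miRNA annotation criteria:

- the mature must sit entirely on one arm of a single stem-loop (no base in
  a terminal loop; duplex partners strictly monotone);
- mature/star duplex mismatches <= 4, with <= 2 nt of total asymmetric
  bulge;
- at least 60% of mature bases paired;
- fold MFE <= -18 kcal/mol;
- terminal loop >= 3 nt.

All thresholds are config values.  The star sequence is placed with the
canonical 2-nt 3' overhang (partners of the mature ends shifted by +2,
frayed ends extrapolated).  A tag passing at any locus counts once, with
the best (lowest-MFE) passing window retained and all loci recorded.  Star
presence is recorded but not required for new miRNAs -- requiring the star
read would be more stringent than the single-library design supports.

Conserved/new classification matches each mature against a mature-miRNA
reference set (a packaged plant mature set by default) under an ungapped
end-to-end distance: Hamming mismatches on the best overlap plus one point
per overhanging base.  A candidate within 2 mismatches of a reference entry
("fewer than 3") is conserved and inherits the reference family; everything
else is new.  New families form by single-linkage clustering at distance
<= 2 and are numbered (`nta-miRn1, ...`) in order of decreasing read
support, with letter suffixes inside multi-member families.  A candidate
whose sequence equals the computed star of a better-supported candidate is
reported as that miRNA's star (`*` suffix).

## Expression and fold changes

Counts are normalized per million clean reads (scale and basis
configurable).  The fold change is max/min of the two normalized counts,
signed `+` when the miRNA is higher after the treatment and `-` when lower.
When exactly one count is zero, the magnitude reported is the nonzero
normalized count itself -- the zero-count convention used in the published
tables this format mirrors -- and both-zero records are dropped rather than
imputed.  Folds are reported at two decimals (half-up); internal values
keep full precision.  "Marked" records are those with magnitude strictly
greater than 2.

A note on the published worked-example rows: recomputing fold changes from
the printed normalized counts reproduces only a subset of the printed fold
values exactly (30 of 72 conserved rows; e.g. one printed 3.73 where the
printed counts give 4.15), indicating the original folds were computed on a
different normalization than the printed counts.  This package defines the
fold as the ratio of the reported normalized counts; worked-example tests
use the self-consistent rows.

## Target prediction

The scanner implements the community-standard plant target-scoring scheme
so that scores are reproducible offline: per-position penalties of 1.0 per
mismatch, 0.5 per G:U wobble and 2.0 per bulged base, each doubled at miRNA
positions 2-13 (5'-counted seed), cutoff 3.0 points.  The comparison is
<= 3.0 by default with a strict-mode flag, and all penalties, the seed
window and the cutoff are config values.  Sites are sought on the sense
strand at every offset, ungapped plus single-gap variants (one bulged base
on either strand); the best alignment per site start is reported.  The
production scanner vectorizes the per-offset accumulation with numpy and is
verified against a brute-force offset-by-offset search.  Hits with a
mismatch or gap at miRNA positions 9-11 (the cleavage-site straddle) are
labelled Translation, otherwise Cleavage; G:U counts as pairing.

## Synthetic study design

The generator emulates the study design end to end so the pipeline runs
with no downloads: a 200 kb random genome with 20 conserved + 10 new
planted hairpins, structural-ncRNA references, 50 transcripts of 500 nt
with one planted target site per planted miRNA (~30% with a central
mismatch for the Translation label), and two 200,000-read libraries.

- Planted matures: conserved ones are packaged-reference entries with 0-2
  substitutions; new ones are random 20-22-mers at distance >= 4 from every
  reference entry.  Precursors are perfect inverted repeats (8-12 nt pads
  and loop) validated against the default criteria before simulation.
- Depths: each miRNA's lower-condition mean depth is log-uniform in
  [300, 2000]; the other condition is that mean times the true fold
  magnitude (cycled from {1, 1.5, 2.5, 3, 4, 6}, alternating direction).
  Counts are Poisson -- a single library per condition, no overdispersion
  (a negative-binomial hook would be the first extension for replicated
  designs).  Star reads are added at 5% of mature depth.
- Background: rRNA 10%, tRNA 8%, snRNA 0.05%, snoRNA 0.03%, repeats 2% of
  each library as reference fragments; the remainder is genomic
  degradation with length modes at 21 and 24 nt.  A uniform 0.1%
  substitution error is applied; 36-nt raw reads carry the 3' adapter.

What passing tests on this bed do and do not show: they demonstrate the
pipeline's bookkeeping, folding, screening, classification, quantification
and scanning are correct under the stated model, with planted-truth
recovery >= 90% and fold estimates within 25% relative error.  They do not
demonstrate robustness to real-data phenomena the generator omits:
isomiR 5'/3' heterogeneity, RNA editing, imperfect planted hairpins,
multi-mapping between near-identical paralogs, adapter dimers, or
non-uniform degradation.  Real catalogs also cannot be reproduced without
the original raw libraries, which were never deposited.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout; minus-strand loci are
reported after reverse complementing.  U maps to T on ingest; case is
ignored.  Ratios and folds print at two decimals, half-up.  Traceback
comparisons in the folding DP use a 1e-6 tolerance.  Sequences shorter
than 8 nt refuse to fold; N-containing precursor windows are skipped.
Empty reference sets, zero library sizes, both-zero expression records and
mature intervals outside the precursor raise errors rather than guessing.

## Problem sizes used by the test suite

The acceptance surface runs the full default study (2 x 200k reads, 30
planted miRNAs) once, plus smaller studies (8k-read libraries, 5 planted
miRNAs) for per-stage tests; folding equivalence uses 500 random sequences
of 8-14 nt against exhaustive enumeration, and scanner equivalence uses 50
planted 150-nt transcripts against brute force.
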