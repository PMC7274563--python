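# Methods

## The retention rule (k-mer screen)

Every 12-bp window of a read is counted on the read's given strand;
windows containing N are skipped entirely. The retention statistic is the
5th order statistic of the count spectrum (equal counts occupy consecutive
ranks), and a read passes iff it is ≥ 8 and the read is ≥ 5000 bp. The
length bound "greater than 5 kb" is implemented inclusively (≥ 5000); the
boundary read costs nothing and is not worth distinguishing.

No reverse-complement canonicalization is applied: a tandem array lies on
one strand of one molecule, and the threshold is calibrated to raw window
counts. The rank statistic is nonetheless strand-symmetric (the multiset
of counts is identical for a read and its reverse complement), which the
tests assert. For a perfect array of a duplicate-free monomer of period
*p* with *m* copies, the count at phase *r* is the number of window starts
congruent to *r* — the closed form used as the test oracle — so the rule
admits arrays of ≥ 8 copies exactly; with ~10% read error the effective
threshold shifts to arrays whose copy number times the 12-mer survival
probability (≈ 0.9¹²) still clears 8, i.e. full-read arrays, which is the
regime the screen is meant for.

## Seed matching and dot plots

Matches are maximal exact word matches (default word 10; both strands
optional), found by indexing target words and merging overlapping hits per
diagonal; maximality is guaranteed because a run of word hits extends
exactly as far as the underlying character run. This replaces
scoring-matrix local alignment deliberately: downstream period estimation
needs only diagonal positions, and at ~10% error exact word-10 seeds still
tile true repeats (each copy pair leaves a seed every few dozen bp). The
transition-tolerant scoring of YASS-style aligners (match +5, transversion
−4, transition −3, gap open −16/extend −4) is recorded here as reference
configuration but intentionally not implemented. Coordinates are 0-based
half-open; a minus-strand match stores the forward-strand start of the
matching target window. Dot plots are PNGs with forward matches green and
reverse purple, scaled to ≤ 1000 px on the longer axis; bytes are
deterministic for fixed input.

## Period estimation

Forward matches above the main diagonal are histogrammed by offset
(t − q), weighted by matched length. Candidate fundamentals are offsets
with support within a factor 0.5 of the maximum bin; the smallest
candidate whose harmonic series {f, 2f, 3f, …} — each multiple with a
jitter band of ±10% of k·f, since indel drift accumulates with harmonic
order — explains ≥ 50% of total support wins. This rejects harmonics (2f
holds only about half the support of an array) and tolerates ~10% indel
error. The returned period is the support-weighted mean offset of the
first harmonic band. Estimation returns nothing when total support is
below min_copies × word.

## Region calling

Each off-diagonal match leaves two read-axis footprints, [q, q+L) and
[t, t+L). Two pre-filters remove chance matches, which would otherwise
chain distant arrays together: a match must have corroborating support at
a similar offset (≥ 3 × word matched bases within ±max(2·word, 5%) of its
offset — true array matches share the unit-length offsets, chance matches
are isolated), and regions are maximal runs where footprint coverage depth
is ≥ 2 (every base of a real array is covered by several copy-pair
footprints; a chance match covers its footprints once). Runs closer than
merge_gap_bp = 500 merge — at word 10 and 10% error, seed gaps inside true
arrays are far below 500 bp, while distinct interspersed patches sit ≥ 1 kb
apart. Each region's period comes from the matches lying wholly inside it,
so matches *between* two arrays of one family contribute to neither.

A region is flagged low-complexity (reported, but excluded from family
work) when its period is < 50 bp or ≤ 10 bp (microsatellite scale), its
geometric copy estimate is < 3, or its support is below 3 supported
copies (support_bp / period < 3). The continuity index is
support_bp / ((copies − 1) × period), clamped to [0, 1]: an error-free
array scores exactly 1 (harmonic support exceeds the denominator and is
clamped), and the index decays with divergence — a quantitative proxy for
how unbroken the parallel diagonals look.

## Pattern classes

NO_TR_LOW_COMPLEXITY if no qualifying region; COMBO if ≥ 2 regions of
different families (labels if known, else periods differing > 10%);
INTERSPERSED if ≥ 2 regions of one family; FULL if one region spans
≥ 90% of the read (full_coverage_frac, configurable — "occupies the whole
read" has no published number); else PARTIAL. On the synthetic study
conditions (units 60–385 bp, ≥ 8 copies, five patterns) classification is
100% correct error-free and ≥ 90% at 10% composite error; period recovery
is within ±10% for ≥ 95% of arrays.

## polySeq catalog

A family block is its consensus tiled to exactly 1000 bp, or 2000 bp for
units > 500 bp so every block still holds ≥ 2 copies and shows diagonals.
Blocks concatenate append-only; offsets never change. Assignment
seed-matches a read (both strands) against the whole polySeq: a block
qualifies when it holds ≥ 10% of all matched bases *and* its matches cover
≥ 20% of the read's repeat region. The coverage gate matters: a single
chance 10-mer shared by a read array and a block is multiplied by copy
number on both sides (20 × 5 occurrences from one word), inflating matched
bases while covering almost nothing of the read. Assignments (including
NEW) are only emitted for reads with a qualifying repeat region, so random
reads can neither join nor found families. New families are registered
idempotently: a consensus within 10% rotation- and strand-aware edit
identity of an existing family's unit (edlib free-end alignment into the
tiled unit) maps to that family. Names are prefix + unit length zero-padded
to three digits (HuluTR060), letter-suffixed on collisions, optionally
"-readid" for read-specific designations. Abundance is reads-per-million
of the unfiltered library, rows sorted by abundance then unit length.
Previously published families (telomere, and the 180/385/335-bp
subtelomeric and 5S rDNA repeats) can seed a catalog; apart from the
canonical plant telomere unit their consensi are synthetic placeholders
that only reserve blocks and names.

## Consensus derivation

The region is cut into fixed windows of the estimated period at the phase
maximizing window-to-window identity. The initial consensus is the single
window that best matches its successor — under indel noise a fixed-width
stack loses phase after a few copies, so a real observed monomer is a
better starting point than the majority of a drifting stack. Refinement
iterates (≤ 10 rounds): segment the region into successive consensus
copies with free-end edit alignment (cut contiguously at the previous
boundary so clipped first bases are not lost), globally align each monomer
to the consensus (match +2, mismatch −2, indel −7 — shipped as printed for
the classic tool's settings even though that tool's own common mismatch
default is 7; all configurable), and rebuild by column majority including
insertion columns, ties resolved to the first monomer's character, winning
gaps dropping the column. The array score is the summed per-monomer
alignment scores; arrays below 50 are suppressed (24 matched bases at +2
score 48 and vanish; 25 score 50 and are reported). Unit lengths round to
the nearest 5 bp, midpoints up. AT% excludes N from both counts. On
100 synthetic 120-bp arrays at 10% error the consensus is within 5% edit
distance of the generating monomer in ≥ 90% of reads (measured: 100%).

## Divergence analysis

Eleven consecutive internal monomers (first and last array copies excluded
as potentially truncated) are taken at consensus phase, choosing the
window closest to the consensus. Identity is 100 × matches / columns of a
global alignment with unit scores, gap columns counted in the denominator
(the conservative Clustal-style reading; a matched-columns denominator is
available). The read-level matrix averages the n² cross pairs off-diagonal
and the n(n−1)/2 within-read pairs on the diagonal — self-pairs excluded,
since identity-100 diagonals would inflate the within-read average. (For
11 + 11 monomers the cross-pair count is 121; a published count of "122"
for this pairing does not correspond to any natural pairing and 121 is
implemented.) Heat maps use a two-color black(40)→yellow(70) ramp.
Monomers are cut at each read's own consensus phase, so between-read cells
mix true divergence with arbitrary relative rotation; within-read averages
are rotation-free and are what the monotonicity tests check.

## Probe design

Per-read consensi of one family are cyclic rotations of each other, so
each is first rotated to maximize word-seed agreement with the first, then
merged into a center-star multiple alignment (pairwise global alignments
to the first sequence, merged on its coordinates). Column conservation is
the modal-base frequency over the non-gap count (0 for all-gap columns);
the contiguous window (default 22 columns; practical oligos run 18–30 nt)
with the highest mean conservation — leftmost on ties — yields the probe:
modal base per column, gap columns dropped. Only consensi from regions
with continuity ≥ 0.5 enter the alignment (diverged arrays make poor
probes). No genome-wide uniqueness or thermodynamic screening is
performed. Probe rows follow the synthesis-table layout: name,
"5'-F-" + sequence, comma-joined fluorophore channel codes (F/R/Y).

## Synthetic data

The generator emulates uncorrected CLR-style reads: default composite
error 10% split 4% substitution / 3% insertion / 3% deletion (only the
total is constrained by the data the conditions emulate; the split is a
fixed, configurable choice), per-base independent, uniform alternatives —
no homopolymer bias or quality values. Monomers are random with a chosen
AT fraction (study range 0.42–0.79) and rejection-sampled until their
cyclic 12-mer spectrum is duplicate-free, giving arrays a clean phase
structure. Reads follow the five pattern layouts (full ≥ 95% occupancy;
partial 20–60%; interspersed/combo arrays ≥ 1 kb apart; low-complexity
microsatellite runs or pure random). Truth intervals are recorded
error-free and mapped through the indel process, never re-detected.
Everything is deterministic per seed. Passing tests on this generator
shows the pipeline's logic is correct under idealized uniform noise and
random flanks; it does not establish performance on real reads, whose
error is bursty and whose flanks contain genuine genomic repetition.

## Problem sizes and numerical choices

The benchmark suite uses 200 reads for period recovery, 100 per pattern
condition, 300 catalog reads + 3000 background for assignment, and 100
reads for consensus accuracy — sizes at which the binomial noise on the
reported rates is ~1–3 points, chosen to keep a full run around a minute.
Ties everywhere break deterministically (leftmost window, smallest offset,
first monomer's base, alphabetical last). Degenerate inputs return empty
results rather than raising where a scan can be vacuous (short reads,
empty histograms) and raise where the request is incoherent (empty
sequences, zero-length axes, too few monomers).

## Known limitations

Detection needs ≥ 3 supported copies and units ≥ 50 bp by default; units
near or above the read length are invisible to both the k-mer screen and
the dot plot. Heavily diverged arrays fragment into low-continuity
regions and may be under-merged. Family assignment assumes the polySeq
blocks are mutually dissimilar; homologous families above ~90% identity
will collapse at registration. The reported reads-per-million uses the
pre-filter library size supplied by the caller and is only as meaningful
as that census.
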