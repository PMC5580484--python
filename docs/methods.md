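# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `snpatlas`.  Coordinates are 0-based half-open internally
and 1-based inclusive in every emitted file (GenBank/GFF3/VCF
convention); the conversion lives in `snpatlas.io` and nowhere else.

## Co-linear alignment

The isolates this pipeline targets share gene order and orientation, so a
reference-anchored star alignment replaces general multiple alignment:

- **Anchors.** All maximal exact matches ≥ 20 bp (configurable) between
  reference and query that occur exactly once in each sequence, found by
  seeding on shared k-mers (k = the length threshold), extending each
  seed maximally, deduplicating per diagonal, and checking uniqueness of
  the full matched substring.
- **Chaining.** Dynamic programming selects a chain of anchors strictly
  increasing in the starts and ends of both sequences.  Partial overlap
  between successive anchors is allowed and trimmed (anchors are exact,
  so trimming preserves correctness).  The objective is the trimmed
  anchored length minus 0.5 × |diagonal change| between successive
  anchors; ties prefer the smaller total inter-anchor gap span.  The
  diagonal-shift term is an indel cost: a true indel of length L shifts
  the diagonal once and costs every crossing chain equally, whereas a
  spurious shift-and-return through a mutated tandem array pays the
  period twice.  Without this term, pure length maximization provably
  prefers period-shifted anchors inside tandem repeats (exact matches
  between *different* repeat copies outlast same-copy matches when
  mutations fall differently per copy), fabricating ±period indel pairs.
- **Gap fill.** Inter-anchor segments are aligned with an affine-gap
  global alignment (Biopython's `PairwiseAligner`): match +2,
  mismatch −3, gap open −5, gap extend −2, a gap run of length L costing
  `open + L·extend`.  IUPAC ambiguity codes score +1 ("half match") when
  the two codes' base sets intersect, so documented consensus
  heterogeneity is not penalized as divergence.  Segments are capped at
  50 kb as a quadratic-blowup guard; in practice inter-anchor segments
  are a few hundred bp.
- **Projection.** Pairwise alignments are merged around the reference;
  insertions at the same reference position share one column block, each
  isolate's insertion left-aligned and gap-padded.  Manual curation of
  repeat-region alignments is deliberately replaced by this deterministic
  left-normalization, so column placement inside repeats is reproducible
  but may differ from a hand-adjusted alignment; SNP records carry an
  `in_repeat` flag so such positions can be excluded.
- The degapping invariant (every row reproduces its input genome exactly)
  is asserted on every construction.

## ORF annotation

ORFs are maximal ATG→stop frames, length counted start through stop
codon inclusive, threshold 150 nt (strict: 147 nt is rejected), ATG-only
starts, stops TAA/TAG/TGA.  Within one stop-bounded frame segment only
the 5′-most ATG is reported.  Filtering drops ORFs wholly contained in a
repeat feature (partial overlap survives) and resolves pairs overlapping
by more than 100 nt by keeping the longer ORF, longest-first — a
deterministic reading of common small-genome annotation practice; exactly
100 nt of overlap is allowed.  Filtering is idempotent.

Naming projects each query ORF through the alignment into reference
coordinates.  A query ORF covering ≥ 50% of each of two adjacent
same-strand reference ORFs is a fusion (`cp28/29`); a reference ORF
claimed by ≥ 2 query ORFs is a fission (`cp36a`, `cp36b`); otherwise the
reference ORF with the greatest reciprocal overlap (≥ 50% of the shorter)
provides the name; reference ORFs with no qualifying query ORF are
reported `absent_in_isolate`.  A homology-rescue step for ORFs failing
the length/overlap criteria is out of scope; a user-supplied whitelist of
names exempt from filtering stands in for it.

## Repeat detection

Maximal exact repeats (direct: sequence vs itself, self-pairs excluded;
inverted: sequence vs its reverse complement, palindromic self-hits
deduplicated) are found by the same seed-and-extend machinery with seeds
≥ 20 bp by default (≥ 4 permitted).  The tests hold this equal to an
independent quadratic oracle that scans every diagonal of the comparison
matrix for match runs.

Mismatch tolerance lives in the clustering step: pair fragments broken by
mutations are rejoined along their diagonal (direct) or anti-diagonal
(inverted), copy intervals merge when they overlap substantially or are
separated by ≤ 25 bp (a dropped sub-seed fragment between two
mismatches) — exactly-touching intervals are kept separate, because that
is the juncture between adjacent tandem copies.  Copies sharing ≥ 80%
alignment identity over ≥ 80% of the shorter unit (forward or
reverse-complement, whichever is better) join one family; families with
≥ 3 copies spanning ≥ 10% of the genome are flagged dispersed.  The
80%/80% thresholds and the ≥ 200 bp "large repeat" bound below are
pragmatic defaults; no published values exist for them.

The major repeat region is the largest tandem array of large
(unit ≥ 200 bp) direct repeats: qualifying pairs (period ≤ 1.25 × unit)
are extended by smaller same-period matches touching the array, so a
copy truncated by a deletion stays inside the span and the reported
length shrinks by the deleted amount.

## SNP map

A SNP is an alignment column where every named isolate has a non-gap
character and ≥ 2 distinct characters occur.  Columns containing any
ambiguity code are recorded as `ambiguous` and excluded from
classification and densities.  Columns where the reference is gapped but
all other isolates are covered cannot carry a reference coordinate and
are reported in a separate insertion-variant table.

Classification against a rooted reference topology, total over all
patterns and invariant to isolate order:

- biallelic 1|4 → `specific:<isolate>`;
- biallelic 2|3 → `shared:<side>`, the side being whichever of the two
  forms a rooted clade when exactly one does, else the 2-isolate side —
  the only rule consistent with labeling the {M,I12} pattern by the pair,
  the {S,I07} pattern by its clade complement M/I12/E2, and the
  non-clade {E2,S} pattern by the pair;
- triallelic with two singleton private alleles against a three-isolate
  majority → one record carrying both singleton annotations
  (`specific:S+I07`);
- everything else → `unspecific`.

Densities divide non-ambiguous SNP counts by the union of ORF spans
(coding) and its complement (non-coding); overlapping ORFs count once.

## Phylogeny

Distances are uncorrected p-distances with pairwise deletion (gap or
ambiguity in either sequence excludes the column for that pair).  At the
sub-percent divergences this pipeline targets, multiple-hit correction
changes distances by < 1% of their value and the uncorrected proportion
is directly checkable by hand, which the oracle tests exploit.

Neighbor joining follows Saitou–Nei with the standard Q criterion and
branch-length formulas; ties in Q break by the lexicographic order of the
clusters' smallest leaf labels.  Negative branch-length estimates are
retained internally and clamped to zero only in Newick output.

Minimum evolution scores a fixed topology by the sum of its OLS
branch-length estimates (negative estimates included), solved by least
squares on the pair-path design matrix.  The search is
close-neighbor-interchange: from the NJ start tree, examine every
topology within topological distance 4 (all single
nearest-neighbor-interchanges and their interchanges), move to the
lowest tree length with a canonical-topology tie-break, repeat to a fixed
point.  A 1-NNI neighborhood is not sufficient: on random 5-taxon
matrices it strands in a local optimum a few percent of the time, while
the distance-4 neighborhood reaches the exhaustive 15-topology optimum on
every tested matrix.

Bootstrap resamples alignment columns with replacement; site patterns are
compressed to unique columns with counts, so each replicate is a
multinomial reweighting and the full pipeline (distances → NJ → CNI) runs
per replicate in microseconds.  Support of a split in the point-estimate
tree is the percentage of replicate trees containing it.  An outgroup
roots the tree for display only; inference is unrooted.

## Synthetic data: what it emulates and what it does not

`simulate_isolate_set` evolves a random ancestor (default 120,816 bp,
GC 45.39% — the basal isolate's values, consistent with the observed
trend of genome growth and GC decline from basal to derived lineages)
along the rooted ladder `((((M,I12),E2),S),I07)`.

- **Substitutions**: per branch, Poisson with mean rate × branch length ×
  sequence length; K2P-style with transition:transversion odds 2:1; a
  site may mutate on more than one branch (needed for homoplastic
  "unspecific" patterns), but at most once per branch.
- **Branch lengths**: expected substitution counts proportional to the
  published per-branch SNP sets (M 2, I12 21, M+I12 38, E2 54,
  M+I12+E2 21, S 101, I07 356), scaled so the expected segregating total
  is ~788 — the published genome-wide SNP count.  Realized totals run
  ~5–10% lower because large deletions remove sites from full coverage.
- **Indels**: rate 0.025 relative to substitutions (~20 events tree-wide),
  sizes drawn from three classes (1 bp / 2–50 bp / 51–1000 bp with
  probabilities 0.4/0.4/0.2, uniform within class), matching the reported
  1 bp – ~950 bp range; indels never clip the genome ends.  Events apply
  right-to-left against the parent sequence so recorded coordinates stay
  in the ancestral frame.
- **Repeats**: 13 dispersed copies of one 75 bp unit, random orientation
  (an inverted-repeat family), plus one 945 bp major region of three
  315 bp tandem copies, placed by deterministic rejection sampling.
- **TEs**: random-sequence insertions of 684 bp (I12) and 715 bp (E2) at
  fixed genomic fractions, emulating the observed transposable elements
  (whose sequences had no known homologs, so random DNA is faithful).

The `TruthTable` records every event in ancestral coordinates plus the
final per-leaf allele at every segregating position, so alignment and
SNP-calling recall are measured against ground truth, not against another
aligner.

What the generator does **not** emulate: consensus heterogeneity within
an isolate (the source of the published "ambiguous" class of 137
positions — the ambiguity-handling code paths are exercised with
constructed fixtures instead), alignment-driven homoplasy in repeat
regions, recombination, and rearrangement (the study system is
co-linear; rearranged input is detected and rejected, not handled).
Passing tests therefore demonstrate correct recovery of a clean
tree-like evolutionary signal; on real data, repeat-region SNPs remain
sensitive to alignment parameters, which is why records carry an
`in_repeat` flag.

## Problem sizes and determinism

Unit and property tests use 8–20 kb genomes; the end-to-end acceptance
test and `scripts/acceptance.py` run the full ~121 kb five-genome study
(simulation, alignment, SNP map, 100-replicate bootstrap) in a few
seconds on one CPU.  All randomness flows through
`numpy.random.default_rng` seeded from the user-facing seed; identical
seeds give byte-identical outputs, and the bootstrap is deterministic
given its seed.  Floating-point tie-breaks (NJ pair choice, CNI
candidate order) are resolved lexicographically so search paths are
reproducible across platforms.

## Known limitations

- The aligner assumes co-linearity; anchor coverage below 50% of either
  genome raises an error rather than attempting rearrangement-aware
  alignment.
- Exact reproduction of a hand-curated repeat-region alignment (and
  hence of SNP coordinates inside repeats) is not guaranteed; totals
  outside repeats are stable.
- ORF counts depend on the stop-inclusive length convention; a
  146+stop = 149 nt frame is excluded where a stop-exclusive convention
  would also exclude it, but conventions differing on the stop codon can
  shift counts by one boundary case.
- The ME search guarantees the global optimum only as far as the CNI
  neighborhood reaches; for ≤ 6 taxa it matched exhaustive enumeration in
  all tests, but no such guarantee exists for large taxon sets.
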