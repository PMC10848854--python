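# Methods

This note documents the models, conventions and numerical choices behind
mitochar, and what its synthetic-data tests do and do not demonstrate.

## Coordinates and annotation arithmetic

All user-facing coordinates are 1-based and inclusive on both ends, the
convention of GenBank flat files and published mitogenome gene tables. The
single conversion to Python slice indexing lives in
`GeneFeature.extract`; everything else works in inclusive arithmetic, so a
feature's size is `end − start + 1` and the spacer after feature *i* of a
start-sorted circular annotation is `start(i+1) − end(i) − 1`, with the
final spacer wrapping the origin as
`genome_length − end(last) + start(first) − 1`. Overlapping neighbours
produce negative spacers and are reported as overlaps, never clipped,
which preserves the tiling identity

    Σ feature lengths + Σ signed gaps = genome length

for any circular annotation. `closure_residual` measures the failure of a
*declared* table to satisfy that identity; zero residual plus zero
size/gap mismatches defines internal consistency. Declared cells that are
blank parse to "absent" and are skipped by the validator rather than
treated as zero — published tables do contain legitimately blank cells.
Origin-spanning features (end < start) are rejected outright: they do not
occur in the data this package targets, and accepting them would silently
break every piece of interval arithmetic downstream.

The validator reports both the raw feature-row count and a distinct-gene
count (copy suffixes stripped from tRNA/rRNA names only, since a trailing
digit in a protein-coding gene name like `Cox1` is gene identity, not copy
number). Published gene tallies vary in how they count duplicated genes,
so both numbers are exposed instead of choosing one.

## Composition and skew

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C), AT content =
(A + T)/(A + T + G + C), computed from occurrence counts on the annotated
coding strand. Ambiguity codes are counted separately and excluded from
every denominator; a zero denominator raises an explicit
`UndefinedStatisticError` at the accessor level and renders as `NA` in
report tables — never a silent NaN. Per-codon-position rows pool the k-th
base of every codon across the protein-coding genes in genome order; a
trailing truncated codon contributes only the positions it has, so the
three position rows always partition the concatenated CDS counts.

Two conventions are configurable because the field is not uniform on
them: terminal stop codons are *included* in class-level PCG
concatenations by default (flag to exclude), and per-position statistics
are computed on the coding strand only — for a mixed-strand genome each
feature is reverse-complemented into its own sense first, which is the
only defensible reading for codon-position statistics.

Report formatting rounds AT% to one decimal and skews to two, with ties
rounded away from zero (`Decimal ROUND_HALF_UP`), matching how published
tables print; internal values keep full precision.

## Codon usage and RSCU

RSCU follows Sharp & Li: RSCU(c) = count(c) · deg(aa) / Σ family counts,
so each synonymous family has mean 1. The default code is NCBI translation
table 5 (invertebrate mitochondrial), taken from Biopython's codon tables:
serine is an eight-codon family (UCN + AGN), AUA encodes Met, UGA encodes
Trp, and the stop class is the two-codon family {UAA, UAG}. Stops are
treated as one degeneracy class like any amino acid, which is how
published oyster codon tables group them.

CDS extraction splits a protein-coding feature into triplets and returns a
trailing 1- or 2-base remainder as an incomplete stop codon (`T`/`TA`,
completed to UAA by post-transcriptional polyadenylation) rather than
dropping it. Counting rules fixed by the arithmetic of published tables:
start codons count as ordinary codons; complete terminal stops count when
`include_stops` is on (the default); truncated stops are never counted —
they are not codons of the code. Families with zero total get RSCU `None`
(undefined), not 0 or NaN. Codons are DNA internally and RNA in all
outputs.

## Gene order and the TDRL model

Orders are label sequences, optionally circular. Circular equivalence is
rotation only — in the target genomes every gene lies on one strand, so
reading direction is fixed; reflection equivalence is deliberately not
applied. Consistent with that, breakpoint distance counts *directed*
adjacencies of A absent from B (circular closure pair included), which
makes distance 0 exactly when two circular orders are rotations of each
other. It is symmetric in value for permutation pairs.

Shared blocks are maximal runs contiguous in both orders; maximality means
inextensible at either end, and blocks whose position sets (in both
orders) sit inside a longer block's are suppressed. With inversion
enabled, a run may match a run of B read backwards (minimum length 2, so
singletons are not spuriously "inverted"). Circular seams are honoured;
the two degenerate full-circle cases (rotation-identical and
reverse-circle-identical orders, where no maximal anchor exists) are
emitted directly as a single covering block.

One TDRL operation duplicates a contiguous segment in tandem and deletes
one copy of each duplicated gene; keeping both copies (to model leftover
duplicates like extra *trnM* genes) is supported in `apply_tdrl` and marks
the second copy with a trailing apostrophe. For duplicate-free linear
orders the minimal TDRL count from A to B is `ceil(log2 r)`, where `r` is
the number of maximal ascending runs of B written in A's index order: one
operation can at most halve the run count, and a halving step always
exists (split the runs into two halves and interleave). This formula — not
trusted on faith — is pinned to an exhaustive breadth-first search over
all single-TDRL products for every permutation of n ≤ 6 in the test
suite. TDRL counts are defined on linear orders; circular genomes are
linearized at a user-chosen start gene first (`Cox1` by convention in the
packaged oyster orders). Orders containing duplicates are refused, since
the run-count argument requires a permutation.

Duplicate-gene discovery compares same-class feature pairs: equal-length
pairs ungapped (Hamming identity, exact for the generator's
substitution-only copies), unequal-length pairs by global alignment
(match = 1, mismatch/gap = 0, identity = matches / longer length).
Default threshold 0.95.

## Synthetic genomes

The generator's default architecture is the packaged oyster genome: the
`hyotissa_like_spec` preset reproduces its 42 features with the published
names, classes, lengths, start/stop codons (including the truncated `T`
stop of *Nad3*), every intergenic spacer (hence the 30,385 bp total and
the 3,901 bp largest gap), codon weights proportional to the published
codon counts, class-level composition targets from the published values
(whole-genome AT 57.2%, AT skew −0.15, GC skew 0.27; tRNAs 56.3%/−0.14/
0.19; rRNAs near 57.6%/−0.03/0.20), and mutated-copy duplicates
(trnM2/trnM3 and trnL2/trnL3 at 2% per-site substitution, rrnS1/rrnS2 at
1% — rates chosen to land clearly above the 0.95 identity threshold, as
"nearly identical" duplications are).

Base emission probabilities are solved in closed form from
(AT content, AT skew, GC skew): P(A) = s(1 + skew_AT)/2,
P(T) = s(1 − skew_AT)/2 and symmetrically for G/C on 1 − s. The solution
is unique on the simplex, so infeasibility (content outside [0, 1], skew
outside [−1, 1], nonzero skew on zero mass) is detected analytically
before any sampling. PCG bodies are drawn codon-wise from the weight table
restricted to sense codons, between a forced start codon and the
directive's stop; a gene length must therefore equal
3 + 3k + len(stop), which the spec validator enforces. Duplicate copies
are substitution-only (no indels) so Hamming identity against the source
is exact. One `numpy` generator seeded from the spec drives everything —
no global random state — and two runs with the same spec are bitwise
identical.

What passing tests on this generator show: the pipeline's arithmetic is
correct on data with known truth, targets are recovered within binomial
sampling error, and the rearrangement machinery inverts the simulated
mechanism. What they do not show: real mitogenomes have
position-dependent composition, structured control regions, tRNA
secondary-structure constraints and indel-bearing duplications, none of
which the generator imitates; agreement on synthetic data is a necessary,
not sufficient, check against real annotation pipelines.

## Problem sizes and numerical choices

Exhaustive oracles are run where exhaustion is feasible and sampled where
it is not: TDRL BFS covers all permutations through n = 6 (873 orders),
shared-block brute force uses random orders up to n = 10, RSCU invariants
use 200 random count tables, and generator recovery uses 20 seeds at
~3,300 sampled codons (a 10 kb CDS), sizes at which the binomial standard
error of RSCU(UUU) is ≈ 0.05 — comfortably inside the ±0.1 acceptance
band while keeping the full suite in seconds. Rounding for all printed
values is half-up via `decimal`; comparisons against published numbers are
made at the table's printed precision (two decimals for RSCU and skews,
one for percentages).

## Known limitations

- Origin-spanning features are rejected, not modelled.
- TDRL step counts require duplicate-free orders; for orders with leftover
  duplicates the statistic is reported as absent with a reason, by design.
- Breakpoint distance and TDRL counts assume the same label set; partial
  overlaps must be filtered by the caller (e.g. drop genes missing from
  one genome before comparing, as done for *Atp8* in the packaged orders).
- The alignment-based identity for unequal-length duplicates is a
  longest-common-subsequence-style score, adequate for near-identical
  copies but not a substitute for a proper aligner on diverged pairs.
- L-strand features are supported (reverse-complement extraction) but the
  packaged reference data is entirely H-strand, so that path is exercised
  only by synthetic tests.
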