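# Methods

## Definitions and conventions

A local alignment A between a database sequence s and a query q pairs a
contiguous span x of s with a contiguous span y of q through an injective,
monotonically increasing mapping.  With map(A) mapped pairs of which
match(A) are identical, the alignment length is |A| = |x| + |y| − map(A),
the match percentage mp(A) = match(A)/|A|, and the error count
E(A) = |A| − match(A) (mismatches plus gap characters).  An HSLA for
thresholds (l, t) is an alignment with |A| ≥ l and mp(A) ≥ t; a *short*
HSLA additionally has |A| ≤ (2−t)·l.

Coordinates are 0-based half-open internally; TSV output is 1-based
inclusive.  An indexed occurrence stores the position of the k′-mer's
*last* character.  mp comparisons against t use exact rational arithmetic
(`Fraction`), so 48/50 ≥ 0.96 is decided without float rounding at the
boundary.

Alignment shape conventions, chosen here because no external contract pins
them down: gap characters may only appear between aligned pairs — an
alignment never begins or ends with a gap.  Without the terminal rule the
objective "maximize |A| subject to mp ≥ t" is degenerate: unmatched
dangling characters would inflate |A| at no benefit.  Both the production
search and the brute-force oracle implement the same conventions, so their
agreement is meaningful.

## Index

The dictionary maps each 2-bit-encodable k′-mer (k′ ≤ 16) to its sampled
occurrence list.  Sampling keeps end positions k′−1, k′−1+w, k′−1+2w, …
per sequence; the phase restarts at each sequence boundary (the anchor is
the first full k-mer — the simplest deterministic choice; nothing
downstream depends on it).  Windows containing an ambiguous base (N) are
skipped entirely, never stored and never matched, mirroring how seeded
aligners avoid false seeds in ambiguous sequence.  The dictionary is a hash
map keyed by the packed integer regardless of k′: in Python a
direct-addressed table of 4^k′ slots would cost memory without improving
the exact-lookup contract.

On an N-free sequence of length n the occurrence count is exactly
⌈(n−k′+1)/w⌉.  The closed-form size prediction 4^k′ + (D − S(k′+1))/w is
provided as printed; a `per_sequence_kmers` variant replaces the numerator
by D − S(k′−1), the exact total k-mer count, and matches a constructed
index exactly whenever w divides each n_i − k′ + 1.  The printed numerator
undercounts by 2 bp per sequence — negligible at genome scale, visible in
unit tests — which is why both forms exist.  A zero numerator is legal
(it arises at the D = S(k′+1) boundary); only a negative one is an error.

The on-disk format is little-endian with magic `SSKI`, a version byte,
(k′, w), the sequence table, and per-k-mer delta-encoded occurrence lists;
loading verifies magic, version and length and refuses truncated files.

## Search

Phase 1: every query k′-mer (no sampling on the query side) is looked up;
each hit is extended greedily in both directions into a MEM; MEMs shorter
than k* are dropped, the rest de-duplicated.  A seed falling inside an
already-extended MEM on the same diagonal is skipped, and a MEM wholly
inside an already-extended alignment's spans is not re-extended — both are
pure de-duplication shortcuts for work whose outcome is already known.

Phase 2: banded unit-cost dynamic programming extends each MEM outward
from both ends (a numba-compiled kernel).  The band is
⌈(1−t)·l⌉ + 2 diagonals around the MEM's diagonal and the per-side error
cap equals the band; each side consumes at most l + band characters.  For
each side and each exact error count e the DP records the maximum match
count (ties: more consumed characters, i.e. fewest gap characters, then
smaller database consumption); a one-sided extension with m matches and e
errors contributes exactly m + e to |A| and i + j − m − e to map(A).
Combining sides, the search keeps the alignment maximizing (|A|, mp, map)
subject to mp ≥ t — the map term breaks exact ties toward substitutions
rather than gap pairs, keeping substitution-only alignments canonical.
If the best alignment reaches |A| ≥ l it is an HSLA; otherwise (|A| ≥ k*)
it is counted as a false positive after its own de-duplication pass.

"Highly overlapping" alignments — ≥ 50% mutual overlap of the shorter span
on both the database and the query side, closed transitively — are
collapsed to one survivor: longest |A|, then highest mp, then smallest
coordinates.  The 50% rule is this package's concretisation of standard
keep-the-best-of-a-pile practice.

The reverse strand is off by default; when enabled the query's reverse
complement is searched as a second query (the index stays canonical) and
results carry a strand flag.

## Analytical models

Both retention models assume alignment positions match independently with
probability t and consider an alignment of database-side length |x| = l.
Kent's model samples the k*-mer itself: T = ⌊(|x|−k*+1)/w⌋ disjoint
sampled words, each an exact match with probability t^k*, giving
1 − (1−t^k*)^T (0 when T = 0).  The BLAST-style model corrects two things:
the sampled word is a k′-mer that must extend into a MEM of length ≥ k*
(p′ = (k*−k′−1)·t^k*·(1−t) + t^k*), and the window count is the exact
two-point phase mixture over T_f/T_c instead of the floor.  The p′
coefficient is configurable (k*−k′−1 as printed, k*−k′ as the left-
extension enumeration implies, k*−k′+1 as sometimes stated); the printed
form is the default so that reported numbers are reproducible under the
conventional reading, and the difference is below 10⁻³ in retention across
the standard parameter grid.  Probabilities are computed with
`log1p`/`expm1` so (1−p)^T is stable for tiny p; the binomial exceedance
uses exact `Fraction` summation.

## Synthetic data

The generator emulates the conditions the models describe: i.i.d. uniform
genomes (GC fraction configurable, default 0.5), and queries that are
contiguous copies of a genome window of length l carrying exactly
m = ⌊(1−t)l⌋ substitutions by default — the hardest, shortest HSLAs — with
optional single-base indels (keeping m + indels within the error budget
keeps |A| ≤ (2−t)l, inside the short-HSLA window).  Substituted bases are
drawn from the three alternatives so a planted mismatch can never silently
match.  Mismatch positions are drawn by uniform rejection sampling;
the Monte-Carlo MAX-MEM distribution (default 10⁶ repetitions) repeats
that placement and records the longest mismatch-free run, while the
enumeration mode walks all C(l, m) placements exactly.

Two deliberate departures from pure randomness keep ground truth
unambiguous: multi-query suites place windows in disjoint slots with ≥ l bp
separation, and the single bases flanking a planted window are re-drawn to
differ from the query's edge bases so the optimal alignment cannot slip
past the window boundary.  Even so, in roughly 0.1% of instances a deeper
flank coincidence within the gap budget yields an alignment one base
longer than the planted one; retention is therefore always measured
against the unsampled (w = 1) search result — which is also how the
retention-rate definition reads — rather than against planted coordinates.

What the generator does not model: repeats, GC isochores, splicing
(queries are contiguous windows), sequencing error profiles.  Passing
tests therefore demonstrate correctness of the machinery and of the
sampling analysis under the stated assumptions, not performance on real
genomes.

## Evaluation

RR, RR_short and FPR are means of per-query ratios against the
hard-sampled baseline; queries with a zero denominator are excluded from
the mean, and a metric with no defined query is reported as absent, not
as 0.  RR_map is all-or-nothing: a mappable query (non-empty truth set)
counts only if *every* one of its HSLAs is found, the conservative
criterion under which the final mapping provably cannot change.  Alignment
identity is exact coordinate equality — adequate because planted truths
are non-overlapping and de-duplication is deterministic.  Query-time
measurement (median of five wall-clock runs) is provided as a utility but
excluded from all automated checks because it is hardware-dependent.

Two brute-force oracles back the tests: an all-MEM diagonal scan, and an
exhaustive unbanded local-alignment DP over every (cell, error count)
with traceback, sharing only the alignment conventions with the production
path — no index, no seeding, no band.

## Problem sizes used in the automated checks

Parameter derivations, model values and the exceedance table are closed
form.  The stochastic checks use: 500 planted instances per (l, t) row for
hard-sampling completeness (w = w₀ vs w = 1 set equality); 100 random
200 bp instances for MEM-oracle equivalence and 100 ≤ 60 bp instances for
alignment-oracle equivalence; 10⁶ Monte-Carlo repetitions vs the 1225-way
enumeration at (l = 50, m = 2), agreement required within total-variation
0.005; and 2000 planted instances per sampling step for the l = 50
retention comparison against the exhaustive phase × placement oracle,
judged within a 99% binomial confidence interval.  The retention genomes
have 1760 possible window placements — a common multiple of every step in
that row — so the sampling phase is exactly uniform and the oracle applies
without a phase-bias correction.

## Known limitations

* The gapped extension is exact only within its band and error cap;
  alignments whose optimal path wanders more than ⌈(1−t)l⌉ + 2 diagonals
  from the seed MEM may be reported sub-optimally.  For the HSLA regime
  (t ≥ 0.9) this is the intended operating range.
* With multiple MEM anchors inside one alignment the extension is run from
  the first non-covered anchor; pathological tandem-repeat structures
  could in principle yield anchor-dependent results.
* Index construction materialises per-sequence k-mer code arrays
  (vectorised numpy); memory is linear in sequence length, appropriate for
  the megabase scale this package targets, not for whole mammalian
  genomes.
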