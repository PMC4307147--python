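# Methods

## Model

`kmerfix` treats error correction as a property of the k-mer count
spectrum of the whole read set. An error-free read sampled from a genome
at local coverage *c* has a count profile (the counts of its
*r* − *k* + 1 left-anchored k-mers) that behaves like a smoothed random
sample around *c*; a sequencing error that is unique within the read set
drops a contiguous block of entries to 1. The corrector therefore never
judges absolute counts — a uniformly low profile is perfectly consistent
with low coverage — and reacts only to abrupt steps between adjacent
entries.

Counting stores each observed k-mer **and** its reverse complement as
separate entries, incremented together at observation time, so a single
lookup is strand-symmetric by construction: `lookup(x) == lookup(rc(x))`
always. Absolute counts are thus twice what a forward-only counter would
report; since the discontinuity test compares counts with counts, the
shared factor cancels. Unique k-mers are pruned after counting and any
absent k-mer reports count 1, which makes pruning observationally
neutral.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k` | 31 | k-mer length; odd (a k-mer then never equals its own reverse complement) and ≤ 31 so a k-mer packs into a 64-bit word. Long enough to step over common short repeats. |
| `abs_threshold` | 3 | fixed component of the discontinuity test; governs low/medium coverage. |
| `rel_threshold` | 0.2 | relative component (fraction of the larger count); governs medium/high coverage. Both inequalities are strict, so the pair (100, 80) is *not* flagged. |
| `max_corrections` | 10 | edits allowed per read before all changes are reverted. |
| `max_indel` | 3 | longest non-homopolymer indel candidate. |
| `filter_threshold` | 0.5 | unique-k-mer fraction above which a corrected read is routed to the low-information output (strict; pairs only when both mates qualify). |
| `homopolymer` | on | run-length correction; recommended off for Illumina data, where multi-base homopolymer errors are vanishingly rare. |

## Numerical and procedural choices

**Evaluation window.** The window rule — "every window k-mer must
strictly improve, through the k-mer containing the base after the error"
— is realised as the two profile indices adjacent to the trusted border,
extending into the erroneous region. For a high-to-low discontinuity at
pair index *d* these are *d*+1 and *d*+2; for a low-to-high site the
window is mirrored and, for indel candidates, the border index is
shifted by the indel length so that old and new k-mer windows end at
equivalent positions. Strict improvement of so small a window is enough
to reject error-propagating edits (an insertion "fixing" a substitution
fails at the second window k-mer) while still allowing multiple
corrections in close proximity. Acceptable candidates are ranked by
(1) the number of consecutive further-improved entries beyond the window
(capped at 2k; beyond an indel the comparison index is clamped, which
can only affect tie-ranking, not acceptability), then (2) the window
count sum, then deterministic tie-breaks: substitution before insertion
before deletion, then lexicographic bases.

**Staged candidate enumeration.** Length-1 candidates are evaluated
first; length-2 and -3 indels only when no shorter candidate is
acceptable. A true n-base indel cannot satisfy the strict window under a
shorter edit, so staging bounds the candidate space (which otherwise
grows as 4^n) without changing outcomes.

**Site processing order.** Sites are attempted left to right; after each
accepted edit the profile and sites are re-derived, which is what lets
two errors within k bases of each other be fixed one at a time. Adjacent
(compound) errors outside homopolymer runs are not corrected: no
single-edit candidate can satisfy the window there, and the read is left
unchanged rather than guessed at.

**Homopolymer rule.** The run implicated by a discontinuity is found by
scanning left from N+1 (low-to-high) or N−1 (high-to-low). Candidate
lengths span ceil(L/2)…2L, with {1, 2} for L = 1. Because homopolymer
errors coincide across reads, erroneous-length k-mers often retain
counts well above 1 and the accurate length can itself look
discontinuous, so acceptance is by maximisation rather than strict
improvement: the chosen length maximises the summed counts of the two
k-mers bordering the run on each side plus every k-mer spanning the
whole candidate run and the two bases following it. Ties prefer the
smallest length change, then the shorter run, so flat evidence keeps the
observed length. Each distinct run is adjusted at most once per read
(runs are identified by their base and left flank, which survive
run-length edits), and the pass runs only after the strict corrector has
exhausted its options, sharing the same revert budget.

**Qualities.** A corrected or inserted base takes the floor of the mean
of its immediate neighbours' qualities (single neighbour at read ends);
deleted bases drop theirs. Quality scores are never *read* by the
corrector — only rewritten.

**Degenerate inputs.** Reads shorter than k are passed through
uncorrected and count as fully uninformative (unique fraction 1) for
filtering. All-N reads collapse to empty reads at preprocessing.
Internal Ns are replaced by the base indexed by a stable 64-bit hash of
(read id, post-trim position) mod 4 — deterministic across processes and
independent of batching — and are thereafter ordinary substitution
errors. Trimmed leading/trailing Ns are not restored on output.

## Simulator

The simulator generates i.i.d. random genomes at a requested GC
fraction, samples uniform error-free reads from both strands (optionally
paired, optionally with a planted exact repeat or a high-copy segment
emulating plasmid-like coverage), and injects errors from per-platform
profiles: `miseq` (substitutions 0.1%/base, indels 0.001%),
`pgm` (substitutions 0.2%, indels 1.5%) and `gs454` (substitutions
0.1%, indels 0.38%). Indel probability inside homopolymer runs of
length ≥ 3 is up-weighted by a bias that grows with run length
(default 24, chosen so that roughly three quarters of PGM-like errors
are homopolymer-associated, as on the real instrument), with weights
normalised per read so the overall indel rate stays at the profile
value; in-run indels are realised as ±1 run-length changes (±2
occasionally for runs ≥ 8). Error injection draws from a stream keyed by
(seed, read index), so results are independent of batching.

What the simulator does **not** model: position-dependent error rates
(real MiSeq errors concentrate toward the 3' end and after GGC motifs),
quality-score distributions (all clean bases get Q35, error bases Q15),
GC-coverage bias, and chimeric reads. Passing tests therefore
demonstrate the correction machinery under idealised uniform coverage
with known truth; real-data behaviour additionally depends on coverage
structure and error clustering that these conditions do not reproduce.

## Evaluation

The evaluator aligns each read to its exact error-free source (known
from the simulator truth) with a banded unit-cost global alignment
(band 30; deterministic tie-breaks preferring mismatch over indel, then
leftmost) and keys errors by (type, source coordinate): present only
before correction → *corrected*; only after → *introduced*; in both →
*uncorrected*. Truth anchoring removes every mapping artifact a
reference-alignment evaluation would carry (soft clipping, ambiguous
placements, start-position tolerances), so its percentages are cleaner
by construction. Reads whose length diverges from the source by more
than the band are counted incomparable. Alignment cost is cross-checked
against an independent quadratic DP and against edlib in the tests.

## Test problem sizes

The recovery suites run at sizes chosen to exercise the statistics
without waste: substitution recovery on a 100 kb genome at 50x and 5x
(150 bp reads, 0.3% substitutions, fixed seeds), homopolymer recovery on
a 40 kb genome at 30x under the PGM profile, filtering with 5% junk
reads at 25x, and repeat-boundary safety with a planted 2 kb repeat and
a ~20-fold high-copy segment. Under these conditions the suite measures
~99.9% substitution recall at 50x (dropping to ~56% at 5x), ~89%
recovery of ±1 run-length errors in runs ≥ 4, with introduced errors
two orders of magnitude rarer than corrected ones.

## Known limitations

* Compound adjacent errors outside homopolymer runs are detected but not
  corrected (by design — the window rule cannot validate them).
* Non-homopolymer indels longer than 3 bases are out of correction
  scope.
* SNP-bearing reads from very low-coverage haplotypes can be "corrected"
  toward a high-coverage alternative; this is rare but inherent to
  coverage-based evidence.
* The counting table lives in memory; at desk scale this is irrelevant,
  but billion-read libraries would need a dedicated external counter.
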