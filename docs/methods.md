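# Methods

## The windowed-GC statistic

For a coding sequence of *L* codons (sense strand, in frame, length 3*L*),
the per-site statistic at codon site *i* (1-based) is the GC percentage of
the 21 bases spanned by codons *i*−3 … *i*+3. The window is fixed at 7
codons / 21 bases: wide enough to describe the stretch a subcloning primer
would bind, narrow enough to keep single-codon edits visible. Interior
values therefore live on the lattice {0, 100/21, 200/21, …, 100} and a
single codon swap moves a site's value by a multiple of 100/21 ≈ 4.76
percentage points.

Sites 1–3 and *L*−2 … *L* have no full window; they repeat the values at
site 4 and site *L*−3 respectively. These edge values are references, not
measurements, and for *L* = 7 every site equals the site-4 value. Between
*L* = 7 and *L* = 12 the two edge rules can touch or overlap; both are
applied independently, which is consistent because they copy existing
interior values rather than compute new ones.

All computation is done in full precision (the profiler uses a cumulative
sum over per-codon GC counts; `windowed_gc` recounts a slice directly, and
the two paths are cross-checked in tests). Rounding to two decimals happens
only at presentation: site tables, TSV exports, change logs and reports.

The mean-GC reference line is the GC content of the *entire original* CDS.
In comparison mode each sequence carries its own mean; after editing, the
original mean remains the plotted reference while the current mean is
available from the current sequence's profile.

### Extrema

A peak (valley) is a maximal run of consecutive sites at least `threshold`
percentage points above (below) the mean, reported at the run's extreme
site, earliest on ties. The default threshold is 15 points: local
deviations beyond ~10–20 points are what make primer design fail, and 15
is a usable middle that the caller can override (`find_extrema(p, t)`).

## Sequence handling

Input is a single-record FASTA or headerless sequence text. Lowercase and
RNA (`U`) are normalized; anything else — IUPAC ambiguity codes, `N`,
multi-record files, non-triplet lengths, fewer than 7 codons — is rejected
with a specific message, because the window statistic is undefined over
ambiguous bases and silent record-picking hides user errors. Reported
coordinates are 1-based (codon sites for profiles and edits, base positions
for pattern hits); internal indexing is 0-based half-open. A trailing stop
codon is profiled like any other codon. Translation uses the standard
genetic code; internal stops warn but do not fail, so partially edited
constructs can still be inspected.

## Codon-usage tables

The table format is one line per codon — `CODON AA FRACTION PER_THOUSAND`
— with `#` comments and an optional `# organism:` header, mirroring the
public codon-usage compilations such tables are transcribed from.
Validation requires all 64 codons exactly once, agreement with the standard
code, per-family fraction sums within 1 ± 0.02 (published tables round to
two decimals), and per-thousand totals within 1000 ± 10. Synonymous
alternatives are sorted by fraction descending with lexicographic codon
tie-breaks so every downstream choice is deterministic.

Three organism tables ship with the package — *Escherichia coli* K-12 (the
default host), *Homo sapiens*, *Saccharomyces cerevisiae* — transcribed
from widely published per-thousand compilations and renormalized for
internal consistency (per-thousand scaled to total exactly 1000; fractions
recomputed per family, rounded to two decimals, largest codon adjusted so
each family sums to 1.00).

## Editing semantics

An edit session records every substitution chronologically with the
windowed GC at the edited site before and after that change (snapshot
semantics, matching per-change plot updates in interactive use; a
final-state view is always available via `site_table`). Substitutions must
be synonymous; the three stop codons form their own family. Substituting a
codon with itself warns and records nothing. Undo pops the last record.
Replaying the log onto the original reproduces the current sequence
bit-exactly, which is the invariant the exports rely on.

## Flattening

The optimizer is a deterministic greedy loop over single synonymous swaps:

1. Score the profile's total out-of-bounds deviation
   Σᵢ max(lo − GC(i), 0) + max(GC(i) − hi, 0).
2. Take the violating site with the largest deviation (earliest on ties)
   and consider every synonymous alternative, with usage fraction at least
   `min_fraction`, for every codon in that site's 7-codon window.
3. Apply the swap with the largest strict reduction in total deviation
   (ties: higher usage fraction, then lexicographic codon, then leftmost
   window position). If the worst site's window admits no improving swap,
   the next-worst violating site is tried before concluding that no
   improving swap exists.
4. Repeat until there are no violations, no improving swap, or
   `max_changes` is reached.

Termination is guaranteed: total deviation is non-negative, lives on the
100/21 lattice, and strictly decreases with every applied swap. The
procedure is a heuristic in the spirit of manual one-codon-at-a-time
adjustment — no optimality claim — and it reports the sites it could not
fix rather than guessing at acceptable residuals. Some proteins make the
default band infeasible outright: alanine, glycine, proline and most
arginine codons cannot drop below two G/C bases, so an Ala/Gly/Pro-rich
stretch has a windowed-GC floor of 14/21 ≈ 66.7% and will always appear in
the residual report for bounds of [40, 60]. Defaults: bounds 40–60% (the
usual primer comfort zone) and `min_fraction` 0.05, which keeps rare codons
— likely to hurt expression — out of the sequence unless the user lowers it.

## Sequence checks

The scanners are exact-match and self-contained. Restriction-site search
expands IUPAC patterns to character classes, scans both strands (minus
hits reported in plus coordinates with the matched string as read on the
minus strand) and collapses palindromic double-hits to a single
plus-strand report. Palindromes are maximal even-length spans equal to
their own reverse complement; tandem repeats are maximal runs of a
primitive unit, reported at their leftmost phase with whole copies only;
inverted repeats are maximal exact arm/mate pairs with a bounded loop.
Nested reports are suppressed in favour of the enclosing span. Dedicated
tools tolerate mismatches in repeats and arms; the exact-match contract
here trades that sensitivity for deterministic, fully testable behaviour,
and is the documented limitation of this module. Scan defaults (palindrome
min length 8, tandem unit ≥ 3 × 3 copies, inverted arm ≥ 8 with loop ≤ 60)
are starting points, not biology, and every one is a keyword/flag.

## Synthetic fixtures

The generator composes codons from pools keyed by GC count per codon
(0 to 3 of 3 bases): GC-poor families (Lys/Ile/Asn/Phe/Tyr) for low
regions, GC-rich ones (Ala/Gly/Pro/Arg) for high regions, mixed pools for
mid regions. `generate_profile_like` follows an arbitrary per-site target
curve using error diffusion on the codon GC counts; for smooth targets in
[20, 80] the achieved interior profile tracks the target within about ±15
percentage points (the window averages 7 codons whose counts quantize to
0–3). Planted motifs overwrite bases verbatim at requested positions.

The generator *chooses the protein* to fit the requested GC shape — it is
test tooling, not a gene designer. Its sequences are uniform-random within
each pool, so they lack the codon-usage bias, amino-acid composition and
long-range structure of real genes. Passing tests therefore demonstrate
the correctness of the arithmetic, the editing invariants and the
detectors on known ground truth; they do not certify expression outcomes
on natural sequences.

## Problem sizes and determinism

The test suite works at 7–300 codons (profiles), ~80 codons × hundreds of
substitutions (editing walks), and 20–60 codons (flattening, checks) —
sizes at which every brute-force oracle is exact and the whole suite runs
in seconds. All randomness is seeded (`random.Random`/fixed Hypothesis
profiles); every library code path is deterministic by design, including
tie-breaks, so identical inputs give byte-identical outputs everywhere.
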