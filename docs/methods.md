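# Methods

## Scope and model

`invbreak` re-implements, as a tested pipeline, the comparative analysis of
fixed paracentric inversions between two related genomes observed through a
marker map: segmentation of a marker hit table into syntenic segments,
signed-permutation rearrangement distance, breakpoint-region delimitation
and narrowing, junction mechanism classification, inversion dating, and
breakpoint-association enrichment statistics. The emulated study design is
a ~34 Mb chromosome carrying one marker per ~13.8 kb on average, with ten
inversions split 7 + 3 across two lineages and one breakpoint shared by a
tandem pair (19 distinct breakpoints, one reuse).

## Segmentation

Hits are retained at e-value ≤ 1e-20 and length ≥ 50 bp on the accepted
chromosome; markers hitting several subjects are dropped unless all their
hits are on the target, and split hits of one marker are concatenated
(same strand, bounded gap; e-value = min, length = sum). Markers are then
ordered by target coordinate and maximal collinear runs of source rank
become segments. Two thresholds govern run construction:

* `k_stray = 1` — out-of-order markers tolerated (and orphaned) inside a
  run. The emulated protocol discarded ~3% of markers without stating a
  rule; a greedy skip of isolated strays reproduces that behaviour
  deterministically.
* `max_rank_jump = 10` — the largest source-rank gap between consecutive
  run members. Without it, two segments that happen to continue the same
  monotone direction across a junction would merge even though the rank
  sequence jumps to a different diagonal of the dot plot; with marker
  dropout creating small rank gaps, a bound of 10 separates true diagonal
  changes (typically ≥ the per-segment marker count, here ≥ 12) from
  dropout gaps (geometric, almost always ≤ 3 at the simulated rates).

Segments with fewer than 9 markers dissolve into orphans unless their
marker set is whitelisted (the generalization of a single fully-sequenced
clone backing an exceptional 2-marker segment). Segment boundaries are the
first/last retained marker coordinates, which makes the inter-segment
regions marker-to-marker intervals, as required downstream.

## Rearrangement distance

The full Hannenhalli–Pevzner treatment is implemented: framed doubling
(+x → (2x−1, 2x), −x → (2x, 2x−1), caps 0 and 2n+1), alternating-cycle
count, interleaving components of gray edges, hurdles among unoriented
components (nesting-minimal components plus the greatest component when it
contains all others), and the fortress case (odd number of hurdles, all
superhurdles — a superhurdle being a hurdle whose deletion promotes
another unoriented component). The cycle-only bound is wrong already for
all-positive permutations such as (+3, +2, +1); hurdles are required.

Correctness is established against an independent breadth-first-search
oracle over the reversal graph: exhaustively for all signed permutations
of n ≤ 4 (and n ≤ 6 during development) and on 1,000 random permutations
of n ≤ 8. The oracle's distance table is indexed by Lehmer rank × sign
mask and built with a numba-compiled BFS (n = 8 has 10,321,920 states; a
pure-Python builder covers n ≤ 6 when numba is unavailable). Fortresses
cannot occur at n ≤ 8, so the fortress branch follows the published
definition; the biological scenarios this package targets (generic
20-segment arrangements) have oriented components throughout.

`sorting_scenario` applies, at each step, the lexicographically smallest
reversal that reduces the exact distance by one. Such a reversal always
exists on an optimal path, the output is deterministic, and replay to the
identity is asserted in tests. O(d·n²) distance evaluations are trivial at
n ≤ 20.

`subtract_inversions` removes a known lineage's inversions from a relative
arrangement: the input permutation lists the target genome in the known
lineage's frame and the knowns are index intervals on that lineage's
evolving arrangement; un-applying them (value relabelling through each
reversal, in reverse order) re-expresses the target in the ancestral
frame, so the remaining distance counts only the target lineage's own
inversions.

## Synthetic data

The generator's defaults are the emulated study conditions: chromosome
length 34,148,556 bp, exponential marker inter-arrival with mean 13,800 bp
(a renewal process spreads markers homogeneously with Poisson variance),
two-lineage scenarios of 7 + 3 inversions over 20 segments with a tandem
pair sharing its middle breakpoint, orphan (spurious relocation) rate 3%
where noise is wanted, and neutral rate 0.0111 substitutions/site/myr.
Segment boundaries are drawn with a minimum separation of 1.5 × 12 ×
spacing so every segment carries at least 12 markers — accepted segments
must be backed by enough hits for the ≥9-marker rule to recover them, and
draws violating the marker minimum are redrawn. Degenerate inversion draws
(compositions that restore an ancestral adjacency, which would merge
segments in the comparative map) are rejected and redrawn; the distance of
an accepted draw is computed, never assigned.

Sequence-level simulation is confined to windows around junctions (default
flank 25 kb per side; tests use 3–9 kb). The parental arrangement reads
`...A|B...C|D...`; inverting B..C yields derived junctions AC (distal) and
BD (proximal). Mechanism decorations:

* `te_ectopic`: a TE copy at each parental locus, in opposite orientations,
  each bounded by its own target-site duplication; recombination between
  the copies leaves chimeric elements whose flanks realize the exchanged
  relation (distal flanks = reverse complements of proximal flanks). An
  optional excision footprint (both termini, no body) can replace the
  proximal copy.
* `staggered_ssb`: the segment spanning each staggered cut is duplicated by
  fill-in, leaving inverted copies across the two junctions; the displaced
  copy can be eroded by deletions (`deletion_fraction`), and copies
  diverge independently for `age_myr` at the neutral rate.
* `clean_dsb`: nothing.

Substitutions are independent-site Jukes–Cantor: a site differs from its
ancestor with probability 3/4·(1 − e^(−4rt/3)).

Orphan markers are emulated by *relocating* a marker's hit to a uniform
random coordinate (rather than adding extra rows), which matches the
observable — markers that end up in no syntenic segment — and keeps one
hit per marker after merging. Hit e-value/length/identity distributions
are configurable summaries (identity ≈ N(83, 5), lengths lognormal around
400 bp, e-values log-uniform below the mapping threshold); they are not
fitted to any empirical distribution and nothing downstream depends on
their shape beyond the filter thresholds.

## Similarity engine

DNA similarity (outgroup narrowing, TE annotation, inverted-duplication
detection) uses a seeded, ungapped local search: exact k-mer seeds
(k = 11), two-sided X-drop extension, per-diagonal seed masking, both
strands. Scores (+2 match / −3 mismatch) convert to e-values via
Karlin–Altschul with λ solved exactly for a uniform background and a fixed
conservative K = 0.35; random 1-kb sequence pairs essentially never reach
the 1e-3 cross-species threshold (asserted in tests). For duplication
divergence the X-drop is raised to 120 so blocks run through mismatch-dense
stretches instead of truncating at them — truncation biases block identity
upward and the age estimate downward. Ungapped extension is adequate
because the simulated divergence process has no indels; on real data the
block-chaining step (below) absorbs alignment breaks.

Protein alignment (duplicate detection, reciprocal best hit) uses
Bio.Align.PairwiseAligner in local mode with BLOSUM62 and affine gaps
(−11/−1); the duplicate e-value cutoff (1e-30) maps to a raw-score
threshold through the published ungapped BLOSUM62 Karlin–Altschul
parameters (λ = 0.267, K = 0.041).

## Breakpoint regions

Initial regions are the marker-to-marker intervals between adjacent
segments (count = segments − 1; abutting segments yield a flagged
zero-length region). Pairing replays the optimal scenario: each reversal's
two cut sites, mapped back through the preceding reversals (gap indices
are involutions under reversals), land on final-frame inter-segment gaps;
a reused gap collects both inversion ids. The higher-coordinate region of
each pair is labelled distal (coordinates begin at the centromere).

Narrowing tiles the region's local matches against each outgroup junction
window, merges tiles within 100 bp, and takes as new limits the end of the
similarity chain anchored at the region start and the start of the chain
anchored at the region end; conflicting (overlapping) chains collapse to
the overlap midpoint. With a TE library supplied, all sequences are
N-masked first — repeats present at both parental loci otherwise produce
coverage across the junction (the emulated protocol maps against a
repeat-masked genome). On simulated data the narrowed interval contains
the true junction in ≥95% of replicates at default parameters, and the
mean narrowed/initial ratio is ≪ 1. Refinement excises from the region
edges the coding spans of genes whose mutual-best ortholog conserves exon
count and span (±25% relative span tolerance — a declared default);
refinement never extends a region and is idempotent.

## Mechanism classification and dating

TE annotation reports library matches ≥ `te_min_match` (default 18 bp at
≥90% identity; 18 keeps the expected count of chance matches in a
10 kb × 1 kb comparison ≪ 1, while footprint analyses can lower it to
12 to recover terminus fragments). Adjacent fragments matching the two
termini of one element with no internal body merge into a composite
footprint. TSD candidates are the flanking words (default lengths 4–12 bp)
of each junction's principal annotation; exchange requires an exact
reverse-complement relation between the two junctions' flanks, in either
the same-side or crossed assignment. Classification precedence: exchanged
TSDs ⇒ ectopic recombination; else inverted duplications between the
junctions (chained blocks at e ≤ 9e-10, gap ≤ 1 kb) that are *absent* from
the parental windows ⇒ staggered breaks + NHEJ; duplications also present
in the parental arrangement are reported as preexisting, not as mechanism
evidence; else undetermined.

Age = K / (2r): the length-weighted p-distance over noncoding duplication
blocks, Jukes–Cantor corrected (a flag exposes the raw distance), divided
by twice the neutral rate because both copies accumulate substitutions
since the event. On 5 kb of noncoding duplication the median relative
error is ≤15% for ages 1–5 myr (asserted); classification accuracy on 200
mixed-mechanism simulated inversions is ≥95% with ≤1% false
ectopic-recombination calls on clean breaks.

## Enrichment statistics

Adjacent gene pairs are duplicates when identity > 33%, hit length > 57%
of the shorter query, and the score passes the 1e-30-equivalent cutoff;
n genes give n−1 intergenic regions. The chi-square statistic is computed
from the closed 2×2 formula (Yates correction N/2, clamped), the Fisher
test enumerates the full hypergeometric support and sums point
probabilities ≤ the observed one (the minimum-likelihood two-sided
convention, which reproduces the published 0.0098/0.0199 and matches
scipy's convention; an exact-rational enumeration oracle confirms it for
every table with N ≤ 40), and the t-test is Student pooled-variance with
Welch behind a flag. By default the chromosome-wide comparison group
*includes* the breakpoint intervals (table [[4,10],[215,3191]], which
reproduces 11.526); the exclusive construction is available behind a flag.

## Problem sizes and determinism

Default test and acceptance runs use: full-scale marker simulations
(~2,500 markers on 34 Mb — markers only, no sequence), junction windows of
3–9 kb flanks, 200 classification replicates, 15 dating replicates, 1,000
random n ≤ 8 permutations against the BFS oracle, and all ~10⁵ Fisher
tables with N ≤ 40. All randomness flows from explicit per-call seeds; no
global state. The acceptance script derives every child seed from its
`--seed` argument.

## Known limitations

* The similarity engine is ungapped; indel-rich real junctions would
  fragment into more blocks than the simulation produces (chaining
  mitigates, alignment-level indel handling does not exist).
* The generator does not simulate whole-genome nucleotide sequence,
  TE transposition dynamics beyond the three junction mechanisms,
  recombination, or indels; passing tests demonstrate correctness of the
  analysis logic under the declared noise model, not robustness to every
  artefact of real assemblies (chimeric contigs, assembly gaps,
  segmental duplications).
* Distance is unichromosomal: no translocations, fissions or fusions.
* Hit e-value/identity emission distributions are plausible summaries,
  not fits.
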