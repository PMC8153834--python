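# Methods

## The dispersion statistic

For a window of length *L* and a target residue set *A*, the 1-based
positions of *A* residues are sorted and augmented with virtual termini at
0 and *L*+1; consecutive differences give *k*+1 gaps for *k* target
residues. The same is done for the complement set *B*, and the two gap
arrays are concatenated. Two identities hold for every window and are
asserted as properties: the combined gaps sum to 2(*L*+1) and there are
exactly *L*+2 of them (an empty set contributes the single boundary gap
*L*+1, which keeps the count uniform). The raw statistic *s* is the
population standard deviation of the combined array (divide by *N*, not
*N*−1).

*s* is normalized against the extrema over all C(*L*, *k*) arrangements of
*k* target residues in *L* positions. The maximum is attained by
clustering all target residues at one terminus (either terminus gives the
same value by reversal symmetry; the N-terminus is used). The minimum is
attained when every combined gap differs from the mean gap by less than
one, i.e. when the residues are maximally interleaved; constructively,
the *smaller* of the two sets is placed at near-equal intervals (its
*m*+1 gaps are floor/ceil of (*L*+1)/(*m*+1), larger gaps N-terminal) and
the complement fills the remaining positions. Note the uniform spacing
must be applied to the minority set: spreading only the target set when it
is the majority leaves oversized complement gaps and does not minimize the
combined standard deviation. Both constructions are validated in the test
suite by exhaustive enumeration of every arrangement for all window
lengths 5–12 and every *k* (about 16,000 arrangements), and by Monte-Carlo
sampling at (*L* = 20, *k* = 8).

When `s_max = s_min` (k = 0, k = L, or a degenerate short window) the
normalization is undefined; `s_norm` is set to 1.0 by convention, so
homopolymeric windows count as maximally dispersed. This is behaviorally
irrelevant for scanning because 100%-composition windows pass
unconditionally. Computed `s_norm` values are clipped to [0, 1] against
floating-point round-off.

## Scanning, merging, trimming

The scanner slides a fixed window (default 20 aa, step 1) and checks, per
window: every residue group at or above its composition threshold
(inclusive, so a window at exactly 40% passes a 40% threshold), and
`s_norm` at or above the dispersion threshold (default 0.5), computed over
the union of all groups. Two escape hatches mirror the intent of
composition-first identification: the dispersion check is skipped when the
combined composition exceeds the midpoint between the summed group
thresholds (capped at 100) and 100% — overridable with an explicit ignore
cutoff — and 100%-composition windows always pass. Non-canonical letters
(X, B, Z, U, O, J) count toward window length but never toward a group,
which biases composition conservatively downward in their presence.

Overlapping passing windows (step 1 makes consecutive passing windows
overlap by *w*−1) are unioned into maximal runs; runs that merely abut are
kept separate. Each merged span is trimmed from both ends until the
terminal residue belongs to the union of groups, then final compositions
and dispersion are recomputed on the trimmed domain. Final values may fall
slightly below the thresholds; this is intentional, since every
constituent window passed strictly. Proteins shorter than the window are
skipped and counted in the log. Coordinates are 1-based inclusive
throughout; output floats are fixed at 4 decimals so repeated runs are
byte-identical.

For throughput, composition is computed for all windows of a protein at
once via cumulative sums, and the dispersion statistic is only evaluated
for windows whose composition already passes (it cannot change the verdict
otherwise); verbose mode scores every window. The extremal bounds are
cached per (*L*, *k*). Scan time is linear in total residue count, which
the tests assert as ratio bands over 1×/4×/16× proteomes (about 8k–120k
residues) rather than absolute wall-clock limits.

## Subclass enrichment

The secondary residue of a window or LCD is the unique most abundant
canonical residue once the primary residue is excluded; ties are treated
as ambiguous and excluded from tallies (the alternative — breaking ties by
a fixed residue order — would silently inflate alphabetically early
residues). Whole-proteome window frequencies `f_wp` are tallied over every
window of every protein, with the total window count as denominator, so
fractions over secondary residues sum to at most 1.

Enrichment of subclass *s* is `E_s = ln OR_s` with
`OR_s = (f_obs/(1−f_obs)) / (f_wp/(1−f_wp))`. Subclasses whose scaled
whole-proteome frequency (`f_wp` × total observed primary LCDs) is below 1
are excluded; subclasses with zero observed LCDs but scaled frequency ≥ 1
receive an imputed observed count of 1 (a conservatively biased estimate).
Degenerate fractions (0 or 1 after imputation) yield NaN rather than
infinite odds ratios. The two-sided Fisher exact test uses the integer
2×2 table `[obs_s, obs_total − obs_s; wp_s, wp_total − wp_s]` of window
counts; Bonferroni correction is applied across the non-excluded tests of
one primary class. In the tests the scipy Fisher p-value is checked
against an independent hypergeometric enumeration oracle on tables with
counts ≤ 50.

The subclass search grid runs the scanner once per ordered
(primary, secondary) residue pair with two single-residue groups at
thresholds 40% / 20% — 20 × 19 = 380 searches. Co-occurrence counts, per
pair of distinct single-residue classes, the proteins containing at least
one LCD of each class such that some pair of them does not overlap in
coordinates; the matrix is symmetric with a zero diagonal. Proteome LCD
content merges overlapping same-class LCDs before counting residues (one
count per class per residue), divides by total proteome residues, and bins
the percentage into half-open intervals (lo, hi] with "none" reserved for
exactly 0 — the printed bin edges would otherwise overlap; the total
content is the sum over classes and may double-count residues shared
between classes.

## Synthetic proteomes

The planted-proteome generator emulates the one feature the scanner's
recall depends on: compositionally biased segments of known class and
position embedded in compositionally diverse background. Defaults: 20
background proteins of 150–350 aa drawn from a uniform profile over the 20
canonical residues (at uniform 5% per residue, a 20-aa window reaching a
40% threshold is vanishingly rare), plus planted 30-aa segments drawn from
the plant class. Rejection sampling against the scan criteria guarantees a
clean null in the background. The flanks of plant-bearing proteins are
drawn from the background profile with the plant-class residues removed,
so trimming can never extend a recovered domain past the planted segment
and recovery can be asserted exactly. A single integer seed governs all
randomness; identical seeds give byte-identical FASTA output.

What the generator does not emulate: realistic proteome length
distributions, realistic residue frequencies and local correlations,
partial-composition (non-homopolymeric) LCDs, or homologous protein
families. Passing the recovery tests therefore demonstrates correctness of
the scan/merge/trim machinery under controlled conditions, not calibrated
sensitivity on real proteomes.

## Problem sizes

The exhaustive dispersion validation covers window lengths 5–12 (≈16k
arrangements); the scaling check uses generated proteomes of roughly 8k,
31k and 123k residues; downstream statistics are exercised on small
constructed tables where every expected value is hand-enumerable. These
sizes make the full suite and the acceptance script run in seconds while
still covering every code path at full fidelity.

## Known limitations

- The original published tool's exact output column names and its
  treatment of non-canonical residues are not printed anywhere; this
  package fixes its own stable header and counts non-canonical letters in
  the window length.
- Whether abutting (non-overlapping) passing runs should co-merge is
  ambiguous; overlap-only merging is implemented.
- Domain counts on real proteomes are sensitive to the proteome release;
  the optional integration test against the yeast reference proteome
  (UniProt UP000002311) only runs when a local FASTA copy is provided.
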