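# Methods

This note documents the models, parameter choices and numerical
conventions behind `orgrearr`, and what the simulation-based tests do and
do not establish about real data.

## Coordinates and circularity

Every position at a module boundary is 1-based inclusive on the forward
strand of the reference. References are stored linear; circular behaviour
is provided where it matters: the mapper index pads the sequence with its
first `read_len − 1` bases so origin-spanning reads are placeable (the
reported position is canonicalized into `[1, N]`), partner search and
homology extension wrap, and depth accumulation wraps read tails past the
origin. The discordant-pair distance rule is deliberately linear
(|pos1 − pos2|), matching a linearized-reference analysis; a genuine
junction at the origin of an intact circular molecule therefore shows up
as one extra far-pair cluster linking the two reference ends, which
downstream consumers can recognize by its coordinates.

## Mapper

The index holds every k-mer (k = 14 by default; k ≥ 8 enforced) of the
padded forward strand as a sorted integer array; lookups are binary
searches, and batches of reads are mapped fully vectorized (window k-mers
→ candidate starts → per-candidate Hamming score → per-read selection).
A read is tried on both strands with `r` evenly spaced window offsets
from 0 to `len − k`; candidates are scored over the whole read with no
gaps, `N` counting as a mismatch against everything. Ties are broken by
smaller forward-strand position, then `+` before `−`, making the mapper a
pure function of its inputs.

The optimality guarantee is conditional and stated as such: the reported
placement is the global minimum-mismatch placement whenever that
placement has at least one mismatch-free tried window. For `h2r3`
(h = 2, r = 3, 150 bp reads) this always holds — two mismatches cannot
intersect three disjoint windows — so strict mapping is exactly
equivalent to an exhaustive scan (tested against one). For `h75r10`
scattered mismatches can defeat all ten windows; the preset exists for
junction reads, whose mismatches are concentrated on one side by
construction, and for those the anchor-side windows are clean. The two
readings of the guarantee (unconditional in one place, conditional in
another) are reconciled here in favour of the conditional one; the
implementation makes no attempt to paper over the heuristic's gap.

Truncation (`chp100_h2r3`) cuts each read to its first 100 bases before
encoding, i.e. removes the 3′ 50 bases; mismatch budgets then apply to
the truncated length.

## Junction calling

*Candidate rule.* A mapped read qualifies when it has strictly more than
3 mismatches and all mismatch offsets (taken in reference orientation)
fall in one half of the read. The half-based reading makes "no
mismatches on the other side" concrete and symmetric; it also caps tails
at 75 bp, which in turn means the matched side is always the longer
("blue") segment and the tail the shorter ("orange") one for the
re-check rule. The junction point is the reference position of the last
matching base traced from the clean end; the tail is carried 5′→3′
walking away from the junction along the rearranged molecule (for
clean-right candidates that is the reverse complement of the left part).

*Clustering key.* `(junction_point, direction)`, where direction
`forward` means the matched side occupies the lower coordinates. Without
direction, head- and tail-anchored reads at one coordinate would mix and
the filled/empty-circle semantics of the circular map would be lost.

*Consensus.* Tails are aligned from the junction. The temporary
consensus takes the plurality base at each position (ties resolved
A > T > G > C) among reads whose prefix still matches, truncating where
prefix-matching support drops below 3; members that disagree with it
anywhere over their overlap are removed; the final consensus is rebuilt
from the survivors and truncated where support drops below 4. A
consequence worth noting: a cluster of three reads can never produce a
final consensus, so the "more than three members" rule is in practice
enforced by the consensus-length criterion first.

*Validation order.* consensus length > 15; survivors > 3 and > half of
the original cluster; unique partner (exact search of the consensus on
both strands, circular wrap, exactly one hit); per-read re-check against
the partner locus (0 mismatches allowed on the longer segment, ≤1 on the
shorter); mate consistency. All inequalities are strict, including the
boundary cases (consensus of exactly 15, survivors of exactly half, pair
separation of exactly 600, events of exactly 50 bp).

*Mate consistency.* The fragment continues past the junction read's 3′
end — into the partner locus when the 3′ end lies in the tail, along the
reference when it lies in the matched segment. The mate must map on the
strand that continuation implies, within `insert_mean + 3·sd` of the
continuation anchor, with one read length of slack on both bounds
because the mate may itself overlap the junction. Insert statistics are
estimated from concordant pairs of the same mapping run (fallback
300 ± 30 when fewer than ten are available). Reads with unmapped mates
are removed, as are reads whose mate maps elsewhere — the filter that
separates genuine junctions from chimeric library artifacts.

*Classification.* With junction end (J, d₁) and partner end (P, d₂):
same-direction ends with an implied event shorter than 50 bp are `del`
(downstream skip of `|P−J|−1` bases) or `ins` (upstream jump creating a
tandem unit of `|P−J|+1` bases; only tandem duplications are detectable,
since an arbitrary insertion has no second locus to map); opposite
directions closer than 70 bp are `pal`; otherwise the maximal identical
flank spanning the junction is computed by bidirectional extension
(left: how far the junction could shift backward with both loci
supplying the same base; right: forward), and the event is `mhr` when
the flank totals ≥3 bases (orientation `same` when d₁ = d₂), else
`unk`. Distances are minimal circular differences on circular
references.

*Breakpoint convention.* Where a homology tract makes several breakpoint
placements equivalent, the caller reports the placement produced by
maximal extension of the matched side — which is what the
minimum-mismatch mapping plus first-mismatch rule yields identically for
every read of a cluster, so the choice is deterministic without any
re-canonicalization. The simulator's truth table computes its expected
coordinates by the same maximal-extension rule directly from the emitted
molecule sequences, which is what makes exact-coordinate scoring
possible.

*mhmr unification.* Each accepted `mhr` entry carries the homology tract
intervals at both loci; entries whose tract pairs agree within 5 bp are
one repeat pair. Slots are labelled by which locus holds the
forward-frame junction (rearrangement 1 vs 2) and by cluster side
(a = forward-anchored, b = reverse-anchored); for direct repeats the two
rearrangements are exactly the two reciprocal products, for inverted
repeats they are the two junctions of the inversion product. All
junction-read candidates — including those discarded by consensus or
mate filters — are then re-examined against each slot's junction (±5 bp,
tail matching the partner continuation with ≤1 mismatch) and the slot
count is the larger of the validated and re-examined counts, so the
unified total can only grow relative to the constituent entries. The
asymmetry ratio is max/min of the two reciprocal totals with the minimum
clamped to 1.

## Discordant pairs

Positions are each mate's leftmost mapped base from the truncated
(`chp100_h2r3`) run. A pair is anomalous when the positions differ by
strictly more than 600 bp or the strands are equal. Clustering is
single-pass and seed-relative: a pair joins the first cluster whose
*seed* (not centroid) satisfies |Δpos1| + |Δpos2| < 500, else it seeds a
new cluster — the published greedy behaviour, order-dependent in
principle but order-independent for events separated by more than twice
the budget. The reported `sd` pools the deviations of both mate
coordinates around their means. This channel cannot see short indels
(the mates stay within normal insert range) and serves as independent
confirmation of distant junctions.

## Depth and copy number

Depth is per-window mean base coverage; the final partial window is
normalized by its true width, so the sum of window values times widths
equals total mapped bases exactly. The mutant/WT ratio is
`(mut_w / wt_w) · (wt_total / mut_total)`; windows with zero WT depth
are NaN and excluded from summaries and plots. Because read totals are
renormalized, a subgenomic deletion at molecule fraction *f* is read off
the track as a span/flank ratio of 1 − *f* (the flanks themselves sit
slightly above 1 as the deleted molecules' reads redistribute); tests
and the acceptance script therefore measure the depression relative to
the flanking level, which has a clean closed form. Windows inside the
kept copy of a collapsed inverted repeat are flagged as doubled-copy,
and `copy_number_adjusted()` halves them. The expected-change track adds
the signed read support of every rearrangement end per window (forward
ends negative: depth should fall clockwise past them).

## Comparison statistics

Events merge across samples on (sorted end pair, category), exact by
default with an optional bp tolerance. Scaled matrices are reads per
million mapped reads. The outside/inside-gene ratio counts both ends of
every rearrangement once and normalizes by the union lengths of feature
and non-feature territory; a category with no inside ends is reported as
a sentinel (dash) rather than a number. The Morisita overlap defaults to
the Morisita–Horn form, which stays valid for scaled (non-integer)
counts; the classical index is available for raw counts.

## Simulator

The generator emulates what the detection stack is sensitive to, at the
study's stated conditions: 50–120 kb circular genomes (default GC 0.35),
dispersed repeats of 3–79 bp in both orientations, A/T homopolymer
clusters, quasi-palindromes with 20–60 bp spacers; molecule populations
with deletions, tandem insertions, repeat-mediated products (reciprocal
pairs at a configurable asymmetry), and linear fold-back molecules;
150 bp pairs from normal inserts (mean 300, sd 30 — a typical spread for
mechanically sheared PCR-free libraries; the source protocol states only
the mean) sampled in proportion to molecule fraction × length, wrapping
circular origins. Errors are substitutions only: the stack is ungapped,
and indel errors would conflate sequencing error with biology. Quality
strings are constant and never read.

What it does *not* emulate: indel sequencing errors, quality-dependent
error profiles, GC or PCR bias (the motivating libraries were PCR-free),
nuclear contamination reads, and heteroplasmy beyond the planted
mixture. Passing tests therefore demonstrate the correctness of the
algorithms under clean substitution noise, not performance on real
libraries with adapter chimeras or mapping-quality pathologies.

The truth table records, for every planted junction, the coordinates of
both detectable clusters (computed by maximal extension against the
reference, including extension through planted repeats) and an expected
support count: read-start density × 60, the number of read placements
whose partner-side tail is between 16 bases (the shortest overhang from
which a >15 bp final consensus can be built) and half the read length
(the candidate rule's ceiling). Events below ~4 expected supporting
reads per cluster are not reliably detectable by construction of the
thresholds.

The standard 20-event panel (`standard_panel`) places 4 events of each
category on a 100 kb genome: one abundant event per category at molecule
fraction 0.15 (~9 expected junction reads per cluster at the 50,000-pair
study scale) and three rare ones at 0.004, far below the detection
threshold — mirroring the hotspot-plus-background structure of
destabilized organelle genomes, whose rearranged molecules can dominate
the population. The abundant same-orientation repeat event is strongly
asymmetric (25:1), as observed for microhomology-mediated products; at
150× the sum of all detectable-event fractions cannot exceed 1, so a
panel in which *every* event cleared the threshold would be
unconstructible — the tiered design is the self-consistent realization
of the stated conditions. The dedicated asymmetry experiment plants a
10:1 mixture and sequences the planted products to ~2000× (202,000
pairs on 10 kb), at which the reciprocal-read ratio estimate is tight
(±0.5) against its [6, 14] acceptance band.

## Numerical and degenerate-input conventions

Consensus ties go A > T > G > C; mapper ties go to the smaller forward
position, `+` first. Empty FASTQ inputs produce valid empty outputs
throughout the pipeline. Zero-length intervals, overlapping
collapse intervals, multi-record FASTA, non-ACGTN characters, mismatched
pair streams and zero-total Morisita vectors raise errors rather than
guessing. Collapse of a duplicate region verifies the copy identity
(reverse-complement by default, byte-identical or either via a flag) so
that restoration is byte-exact. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give identical
genomes, reads, mappings and output files.

## Known limitations

Events inside a collapsed inverted-repeat copy are reported on the
collapsed coordinate system and cannot be assigned to a copy. Insertions
of novel (non-tandem) sequence are undetectable by design. Junctions
whose partner consensus is not unique on the reference (e.g. within long
repeats) are rejected rather than rescued. The discordant-pair channel
flags circular-origin pairs on intact molecules as far-anomalies (see
above). Mapping is single-reference; competitive mapping against a
nuclear background is out of scope.
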