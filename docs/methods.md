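# Methods

## Model

A plant mitochondrial genome assembled as a circle of length L is treated as
one conformation of a molecule population.  Each exact repeat pair
(copies *a* and *b*) interconverts four local arrangements: the reference
contexts `aa` and `bb` (each copy between its own flanks) and the recombined
contexts `ab` and `ba` (flanks exchanged).  The recombination frequency of a
pair is the molar fraction of recombined molecules, estimated as the
fraction of conformation-discriminating read pairs supporting `ab`/`ba`:

    f = (N_ab + N_ba) / (N_aa + N_bb + N_ab + N_ba)

Under uniform per-base fragment sampling this estimator is unbiased for the
molar fraction: a reference circle exposes its two reference junctions
exactly as often, per molecule, as the recombined state (two subgenomic
circles for a direct pair, one isomeric circle for an inverted pair) exposes
its two recombined junctions, because molecule choice is weighted by length
within a state and junction hit probability is inversely proportional to
molecule length.  f ≈ 0.5 indicates recombinational equilibrium (equimolar
stoichiometry); the report carries |f − 0.5| with a 95% Wilson score
interval and leaves the interpretation to the reader.  Wilson was chosen
because support counts can be small and frequencies can sit near 0 or 1,
where Wald intervals degenerate.

## Coordinates and repeat detection

Coordinates are 0-based half-open on the forward strand of the deposited
sequence; extraction wraps through the origin, and all operations are
rotation-invariant (the linearization origin of a circular molecule is
arbitrary).  `N` matches nothing, not even another `N`, so ambiguity runs
terminate repeats.

`find_repeats` reports literal **maximal exact repeats**: k-mer seeding
(k = min(31, min_len), refusing min_len < 8 where seeding degenerates) over
the circular sequence, bidirectional extension in both orientations, and
deduplication by canonical coordinates.  Copies sharing a canonical sequence
(the lexicographic minimum of forward and reverse complement) are grouped
into units named R1, R2, … by descending length, ties broken by leftmost
start.  A unit's copy set is jointly maximal — no extension keeps all copies
identical — though an individual pair of copies inside a ≥ 3-copy unit may
extend further on its own; such longer extensions surface as their own
units.  Sub-repeats wholly embedded in a longer unit's copies are not
reported separately unless an additional copy elsewhere makes them maximal.
A perfect palindrome is reported as one unit whose two copies share
coordinates on opposite strands, overlapping itself over its full length.
Match length is capped at L for fully periodic circles (an arbitrary
anchoring; such inputs do not occur in practice).

The test suite checks the finder against an exhaustive, algorithmically
unrelated oracle: compare the circle with every rotation of itself and of
its reverse complement and read off maximal equality runs.

Genome-wide summaries count repetitive content as the union of copy
intervals (a base in several copies counts once); GC is (G+C)/(A+C+G+T)
with `N` excluded from the denominator.  Reproducing unit/copy counts
published for a specific assembly depends on the maximality convention of
the tool used there; the exact-repeat convention here is the one specified
above.

## Conformation construction

Each conformation is `left flank + repeat + flank`, with flanks of up to
300 bp (default, matching a 300 bp insert: both junctions of any repeat
short enough to assess fit inside one conformation).  Conformations are
written in the reading direction of copy *a* on the genomic forward strand;
for an inverted pair, copy *b*'s context enters reverse-complemented into
that frame, so `ab` = leftFlank(a) + repeat + revcomp(leftFlank_genomic(b)).
Flanks are kept single-copy: if another repeat copy begins within the flank
window, the flank stops at its boundary and the truncation is recorded.  A
copy whose flanks are entirely covered by other repeat copies cannot be
discriminated and is rejected with a suggestion to shrink `flank_len`.
Zero-length flanks produce degenerate (identical) members and are flagged.

**Shared-copy (overlapping) pairs.**  When one copy of pair P shares
`o ≥ 1` bases with one copy of pair Q, the flank of P's shared copy on the
overlap side necessarily runs through Q's copy, and its continuation beyond
that copy is ambiguous: the native genomic sequence, or — if Q has itself
recombined — the sequence beyond Q's *other* copy's matching end.  Both
variants are enumerated, giving 3 reference + 3 recombined members per pair
(labels `bb.r`/`bb.x` etc. encode which partner context is used).  This
member-construction rule is this package's convention, implemented
generically for any `o ≥ 1` that does not span an entire copy.  Read support
is summarised as reference vs recombined totals across the three members of
each kind.

**Whole-genome products.**  For a direct pair with copies at [s1,e1) and
[s2,e2) (copy a rotated to the origin), the products are the circles
[s1,s2) and [s2,s1) — each keeps one repeat copy, lengths sum to L.  For an
inverted pair the product is the circle with [e1,s2) reverse-complemented —
same length, double-stranded base pairing conserved.  Re-recombining the two
direct products at their shared leading repeat regenerates a rotation of
the parent.  Pairs with overlapping copies are not decomposed.

## Read assignment

The aligner is deterministic, gapless and local: 15-mer seeds (three probes
per mate: start, middle, end) anchor candidate diagonals; on each diagonal
the best segment under +1 match / −4 mismatch scoring is found by a
vectorised maximum-subarray scan, and segments with a mismatch rate above
`max_mismatch_rate` (default 2%) are discarded.  Mates are paired in FR
orientation; an external SAM-producing mapper is deliberately not required,
which makes the ≥ 100 bp aligned-length filter exact and the whole path
reproducible.

A pair supports a member iff

1. its summed pair score on that member is strictly greater than on every
   other member and every decoy sequence (ties are never broken — they are
   counted `ambiguous`; a decoy tie counts as `filtered_decoy`);
2. each mate aligns over ≥ `min_aln` = 100 bp (suppresses partial
   nuclear-homology alignments);
3. the mates jointly cover both flank–repeat junctions with ≥ `min_anchor`
   = 25 aligned bases beyond each junction into flank sequence ("spanning"
   operationalised: without junction coverage a read cannot discriminate
   conformations).  A pair is counted once regardless of which mate(s)
   provide the junction coverage.

`min_anchor` = 25 makes a 150 bp mate in a 300 bp flank comfortably
discriminative while excluding few-bp overhangs.  The anchor also sets the
assessability rule: a pair is short-read assessable iff
`repeat_length ≤ insert_size − 2·min_anchor` (a fragment must bridge both
junctions with anchors); a ~16 kb repeat at a 300 bp insert is flagged
unassessable rather than estimated.

Counters are disjoint: every input pair lands in exactly one of the member
counters, `ambiguous`, `filtered_short`, `filtered_decoy` or `unmapped`.

## Synthetic data

The generator emulates the targeted study conditions: 150 bp paired-end
reads, insert ~N(300, 30²) (the insert SD is not part of the published
geometry; 10% of the mean is a typical library width), background GC 43.5%
(mitogenome-like), and planted exact repeat pairs placed with ≥ 400 bp
separation so 300 bp flanks stay single-copy.  Backgrounds are
rejection-checked with the repeat finder so exactly the planted structure is
present.  Fragments are drawn uniformly per base from a molecule population
with recombined molar fraction `f`; errors are substitutions only, matching
the gapless assignment engine (no indel model in v1).  Contaminants: whole
pairs from a plastid-like decoy circle (20 kb, 38% GC), and nuclear-like
chimeras sharing a 70 bp stretch with the repeat locus (below the 100 bp
aligned-length filter).  All randomness flows from one seed; equal
configurations give byte-identical reads.

What the simulation does *not* model: platform error profiles, indels,
coverage bias, heteroplasmy beyond the two-state mixture, and partially
homologous (non-exact) repeats.  Passing closed-loop tests therefore
demonstrate correctness of the counting and estimation machinery under the
stated geometry, not robustness to every artefact of real libraries.

## Problem sizes and numerical choices

Closed-loop calibrations run on 10–20 kb circles with 2,000–12,000 read
pairs — at a 300 bp insert and 25 bp anchors only fragments in a ~50 bp
window per junction discriminate, so these depths yield tens of informative
pairs, and recovery is asserted within 3 binomial standard errors of the
truth (at f = 0 with error-free reads the estimate must be exactly 0).
The oracle comparison uses 50 random 2–3 kb circles with planted direct,
inverted and origin-spanning repeats.  Frequencies are reported to one
decimal percent (single rounding of the full-precision value); internal
values keep full precision.

## Known limitations

- Exact repeats only; diverged repeat pairs (≠ 100% identity) are outside
  the detection model.
- The shared-copy conformation labelling follows this package's convention;
  other tools may enumerate the 3+3 members differently, though the
  reference/recombined totals are convention-independent.
- The assignment engine is gapless; indel-rich reads lose score linearly
  and may fall to `ambiguous`/`unmapped` rather than being placed.
- Decomposition assumes non-overlapping copies on one circle; nested or
  overlapping copy geometries are refused explicitly.
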