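"""Local conformation sequences and whole-genome recombination products.

For each repeat pair the package builds four local *conformations*: the two
reference arrangements ``aa`` and ``bb`` (each copy in its own flanking
context) and the two recombined arrangements ``ab`` and ``ba`` (flanks
exchanged across the copies).  Each conformation is the repeat itself plus up
to ``flank_len`` (default 300 bp) of single-copy sequence on both ends; reads
are later assigned to these sequences to count support for each arrangement.

Orientation convention: every conformation is written in the reading
direction of ``copy_a``.  For an inverted pair, ``copy_b``'s context is taken
on its own strand, so its flanks enter the conformation reverse-complemented
into that common frame.  Flanks are kept single-copy: if another repeat copy
begins within ``flank_len``, the flank stops at its boundary and the
truncation is recorded.

Two units sharing genomic bases in one copy (an overlapping-copy locus) make
the overlap-side context of the shared locus ambiguous between two variants
-- the native genomic continuation, and the continuation after the partner
pair has itself recombined.  Enumerating both variants yields three reference
and three recombined members per pair instead of two and two.

Whole-genome products: recombination across a direct pair splits the circle
into two subgenomic circles, one repeat copy each; across an inverted pair it
reverse-complements the segment between the copies, giving an isomeric circle
of identical length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .repeats import RepeatCopy, RepeatPair, _interval_segments, circular_overlap
from .sequence_io import CircularGenome, revcomp

logger = logging.getLogger(__name__)

REFERENCE = "reference"
RECOMBINED = "recombined"


class FlankError(ValueError):
    """Raised when single-copy flanks cannot be constructed."""


@dataclass
class Conformation:
    """One local arrangement: left flank + repeat + right flank.

    ``left_junction`` / ``right_junction`` are the offsets of the flank-repeat
    boundaries within ``sequence`` (first repeat base / one past the last).
    """

    label: str
    kind: str  # REFERENCE or RECOMBINED
    sequence: str
    left_junction: int
    right_junction: int
    truncated_left: int = 0
    truncated_right: int = 0


@dataclass
class ConformationSet:
    pair_id: str
    flank_len: int
    members: list[Conformation]
    degenerate: bool = False  # zero-length flanks make members indistinguishable

    @property
    def reference_members(self) -> list[Conformation]:
        return [m for m in self.members if m.kind == REFERENCE]

    @property
    def recombined_members(self) -> list[Conformation]:
        return [m for m in self.members if m.kind == RECOMBINED]

    def __getitem__(self, label: str) -> Conformation:
        for m in self.members:
            if m.label == label:
                return m
        raise KeyError(label)


@dataclass
class GenomeProduct:
    pair_id: str
    orientation: str
    products: list[CircularGenome]


def _covered_array(L: int, copies, exclude=()) -> np.ndarray:
    """Boolean mask of genomic bases lying inside any repeat copy."""
    mask = np.zeros(L, dtype=bool)
    skip = {(c.start, c.end, c.strand) for c in exclude}
    for c in copies or ():
        if (c.start, c.end, c.strand) in skip:
            continue
        for s, e in _interval_segments(c.start, c.end, L):
            mask[s:e] = True
    return mask


def _allowed_extent(L: int, boundary: int, step: int, flank_len: int,
                    blocked: np.ndarray) -> int:
    """How far a flank may grow from ``boundary`` before hitting a repeat copy.

    ``step=+1`` grows rightwards starting at ``boundary``; ``step=-1`` grows
    leftwards starting at ``boundary - 1``.
    """
    for off in range(flank_len):
        p = (boundary + off) % L if step > 0 else (boundary - 1 - off) % L
        if blocked[p]:
            return off
    return flank_len


def _copy_flanks(genome: CircularGenome, copy: RepeatCopy, flank_len: int,
                 blocked: np.ndarray, direction: str) -> tuple[str, str, int, int]:
    """(left flank, right flank, trunc_left, trunc_right) in reading order.

    ``direction`` is the reading direction of the copy within the common
    conformation frame; on '-', the genomic segment after the copy becomes
    the (reverse-complemented) left flank.
    """
    L = genome.length
    if direction == "+":
        m_left = _allowed_extent(L, copy.start, -1, flank_len, blocked)
        m_right = _allowed_extent(L, copy.end % L, +1, flank_len, blocked)
        left = genome.window(copy.start - m_left, m_left, "+")
        right = genome.window(copy.end, m_right, "+")
    else:
        m_left = _allowed_extent(L, copy.end % L, +1, flank_len, blocked)
        m_right = _allowed_extent(L, copy.start, -1, flank_len, blocked)
        left = genome.window(copy.end, m_left, "-")
        right = genome.window(copy.start - m_right, m_right, "-")
    return left, right, flank_len - m_left, flank_len - m_right


def build_conformations(
    genome: CircularGenome,
    pair: RepeatPair,
    flank_len: int = 300,
    all_copies=None,
) -> ConformationSet:
    """Reference (aa, bb) and recombined (ab, ba) members for one pair.

    ``all_copies`` (all repeat copies of the genome) enables flank truncation
    against neighbouring repeats; if omitted, only the pair's own copies are
    considered.  Fails when a flank would consist entirely of the pair's other
    copy -- such flanks carry no single-copy signal.
    """
    if pair.overlap_bp > 0 and pair.overlap_partner != pair.pair_id:
        raise ValueError(
            f"pair {pair.pair_id} shares bases with {pair.overlap_partner}; "
            "use build_overlap_conformations"
        )
    L = genome.length
    copies = list(all_copies) if all_copies else [pair.copy_a, pair.copy_b]
    a, b = pair.copy_a, pair.copy_b
    # conformation frame: copy_a read on the genomic forward strand; copy_b
    # oriented to spell the same repeat sequence
    b_dir = "+" if pair.orientation == "direct" else "-"
    r = genome.window(a.start, a.length, "+")
    rb = genome.window(b.start, b.length, b_dir)
    if r != rb:
        raise ValueError(f"pair {pair.pair_id}: copies disagree ({r[:20]}... vs {rb[:20]}...)")

    blocked_a = _covered_array(L, copies, exclude=[a])
    blocked_b = _covered_array(L, copies, exclude=[b])
    la, ra, tla, tra = _copy_flanks(genome, a, flank_len, blocked_a, "+")
    lb, rb_, tlb, trb = _copy_flanks(genome, b, flank_len, blocked_b, b_dir)
    if flank_len > 0 and (len(la) == len(ra) == 0 or len(lb) == len(rb_) == 0):
        raise FlankError(
            f"pair {pair.pair_id}: flanks not single-copy; try a smaller flank_len"
        )

    def conf(label, kind, left, right, tl, tr):
        return Conformation(label, kind, left + r + right,
                            len(left), len(left) + len(r), tl, tr)

    members = [
        conf("aa", REFERENCE, la, ra, tla, tra),
        conf("bb", REFERENCE, lb, rb_, tlb, trb),
        conf("ab", RECOMBINED, la, rb_, tla, trb),
        conf("ba", RECOMBINED, lb, ra, tlb, tra),
    ]
    degenerate = flank_len == 0 or members[0].sequence == members[2].sequence
    if degenerate:
        logger.warning("pair %s: conformations are degenerate (flank_len=%d)",
                       pair.pair_id, flank_len)
    return ConformationSet(pair.pair_id, flank_len, members, degenerate)


def _overlap_side(genome_length: int, shared: RepeatCopy, partner: RepeatCopy) -> str:
    """Which genomic end ('left'|'right') of ``shared`` the overlap sits on."""
    L = genome_length
    right_base = RepeatCopy(shared.unit_id, (shared.end - 1) % L, (shared.end - 1) % L + 1, "+")
    left_base = RepeatCopy(shared.unit_id, shared.start, shared.start + 1, "+")
    at_right = circular_overlap(right_base, partner, L) > 0
    at_left = circular_overlap(left_base, partner, L) > 0
    if at_right == at_left:
        raise ValueError("overlap geometry not resolvable to a single copy end")
    return "right" if at_right else "left"


def _variant_flanks(
    genome: CircularGenome,
    shared: RepeatCopy,
    partner_shared: RepeatCopy,
    partner_other: RepeatCopy,
    flank_len: int,
    blocked: np.ndarray,
) -> tuple[str, str]:
    """The two overlap-side flank variants of the shared-locus copy.

    The flank beyond ``shared`` (in its reading direction on the overlap side)
    first traverses the remainder of ``partner_shared``; past that copy the
    continuation is either the native genomic sequence (reference context of
    the partner pair) or the sequence beyond ``partner_other``'s matching end
    (partner-recombined context).
    """
    L = genome.length
    o = circular_overlap(shared, partner_shared, L)
    rem = partner_shared.length - o
    side = _overlap_side(L, shared, partner_shared)
    # genomic traversal direction away from the shared copy through the partner
    step = +1 if side == "right" else -1
    strand = "+" if step > 0 else "-"

    if step > 0:
        part1 = genome.window(shared.end, min(rem, flank_len), strand)
        exit_pos = partner_shared.end  # first base past the partner copy
    else:
        n1 = min(rem, flank_len)
        part1 = genome.window(shared.start - n1, n1, strand)
        exit_pos = partner_shared.start  # one past, moving leftwards

    tail = flank_len - len(part1)
    if tail <= 0:
        return part1[:flank_len], part1[:flank_len]

    def continuation(boundary: int, step_: int) -> str:
        m = _allowed_extent(L, boundary % L if step_ > 0 else boundary % L,
                            step_, tail, blocked)
        if step_ > 0:
            return genome.window(boundary, m, "+")
        return genome.window(boundary - m, m, "-")

    native = continuation(exit_pos % L, step)

    # partner-recombined continuation: exit through partner_other instead.
    # Orient partner_other so it spells partner_shared as read along the
    # traversal direction.
    trav = genome.window(partner_shared.start, partner_shared.length, strand)
    fwd_other = genome.window(partner_other.start, partner_other.length, "+")
    if trav == fwd_other:
        other_dir = "+"
    elif trav == revcomp(fwd_other):
        other_dir = "-"
    else:
        raise ValueError("partner copies disagree in sequence")
    if other_dir == "+":
        recombined = continuation(partner_other.end % L, +1)
    else:
        recombined = continuation(partner_other.start, -1)

    # reading order: for step=-1 traversal the pieces were extracted on '-',
    # already in reading order (part1 then continuation).
    return part1 + native, part1 + recombined


def build_overlap_conformations(
    genome: CircularGenome,
    pair1: RepeatPair,
    pair2: RepeatPair,
    flank_len: int = 300,
    all_copies=None,
) -> tuple[ConformationSet, ConformationSet]:
    """Conformation sets (3 reference + 3 recombined each) for two pairs that
    share genomic bases in one copy.

    With ``overlap_bp == 0`` this falls back to the ordinary 2+2 construction
    for both pairs.
    """
    if pair1.overlap_bp == 0 or pair2.overlap_bp == 0:
        return (
            build_conformations(genome, pair1, flank_len, all_copies),
            build_conformations(genome, pair2, flank_len, all_copies),
        )
    return (
        _one_overlap_set(genome, pair1, pair2, flank_len, all_copies),
        _one_overlap_set(genome, pair2, pair1, flank_len, all_copies),
    )


def _one_overlap_set(genome, pair, partner, flank_len, all_copies) -> ConformationSet:
    L = genome.length
    copies = list(all_copies) if all_copies else [
        pair.copy_a, pair.copy_b, partner.copy_a, partner.copy_b
    ]
    # identify the overlapping copy of each pair
    best = None
    for cp in (pair.copy_a, pair.copy_b):
        for cq in (partner.copy_a, partner.copy_b):
            ov = circular_overlap(cp, cq, L)
            if ov > 0:
                best = (cp, cq, ov)
    if best is None:
        raise ValueError("pairs do not overlap")
    shared, partner_shared, o = best
    if o >= min(shared.length, partner_shared.length):
        raise ValueError("overlap spans an entire copy: unsupported")
    other = pair.copy_a if shared is pair.copy_b else pair.copy_b
    partner_other = (
        partner.copy_a if partner_shared is partner.copy_b else partner.copy_b
    )

    # frame: the non-shared copy read genomic-forward; the shared copy
    # oriented to spell the same repeat sequence
    shared_dir = "+" if pair.orientation == "direct" else "-"
    r = genome.window(other.start, other.length, "+")
    blocked_other = _covered_array(L, copies, exclude=[other])
    lo, ro, tlo, tro = _copy_flanks(genome, other, flank_len, blocked_other, "+")

    # non-overlap-side flank of the shared copy: ordinary single-copy rule
    blocked_shared = _covered_array(L, copies, exclude=[shared])
    ls_full, rs_full, _, _ = _copy_flanks(genome, shared, flank_len,
                                          blocked_shared, shared_dir)

    # overlap-side flank of the shared copy: two context variants, built
    # ignoring the partner copy it legitimately runs through
    blocked_var = _covered_array(L, copies, exclude=[shared, partner_shared,
                                                     partner_other])
    var_native, var_recombined = _variant_flanks(
        genome, shared, partner_shared, partner_other, flank_len, blocked_var
    )

    genomic_side = _overlap_side(L, shared, partner_shared)
    # map genomic side to reading side of the shared copy
    reading_side = genomic_side if shared_dir == "+" else (
        "left" if genomic_side == "right" else "right"
    )

    def conf(label, kind, left, right):
        return Conformation(label, kind, left + r + right, len(left),
                            len(left) + len(r))

    if reading_side == "right":
        lsh = ls_full
        members = [
            conf("aa", REFERENCE, lo, ro),
            conf("bb.r", REFERENCE, lsh, var_native),
            conf("bb.x", REFERENCE, lsh, var_recombined),
            conf("ab.r", RECOMBINED, lo, var_native),
            conf("ab.x", RECOMBINED, lo, var_recombined),
            conf("ba", RECOMBINED, lsh, ro),
        ]
    else:
        rsh = rs_full
        # the variants were built reading away from the copy; as left flanks
        # they enter the conformation reverse-complemented
        vn, vx = revcomp(var_native), revcomp(var_recombined)
        members = [
            conf("aa", REFERENCE, lo, ro),
            conf("bb.r", REFERENCE, vn, rsh),
            conf("bb.x", REFERENCE, vx, rsh),
            conf("ba.r", RECOMBINED, vn, ro),
            conf("ba.x", RECOMBINED, vx, ro),
            conf("ab", RECOMBINED, lo, rsh),
        ]
    return ConformationSet(pair.pair_id, flank_len, members)


def recombine_genome(genome: CircularGenome, pair: RepeatPair) -> GenomeProduct:
    """Predict the whole-genome product(s) of recombination across a pair.

    Direct orientation splits the circle into two subgenomic circles, each
    retaining one repeat copy; their lengths sum to the parent's.  Inverted
    orientation yields one circle of identical length with the inter-copy
    segment reverse-complemented.
    """
    L = genome.length
    a, b = pair.copy_a, pair.copy_b
    if circular_overlap(a, b, L) > 0:
        raise ValueError("copies overlap each other: unsupported")
    # rotate the frame so copy_a starts at 0; b then lies wholly inside
    rot = genome.rotated(a.start)
    alen = a.length
    bstart = (b.start - a.start) % L
    bend = bstart + b.length
    if bstart < alen or bend > L:
        raise ValueError("copies overlap each other: unsupported")
    if pair.orientation == "direct":
        p1 = CircularGenome(f"{pair.pair_id}|sub1", rot.seq[:bstart])
        p2 = CircularGenome(f"{pair.pair_id}|sub2", rot.seq[bstart:])
        return GenomeProduct(pair.pair_id, "direct", [p1, p2])
    inverted = (
        rot.seq[:alen]
        + revcomp(rot.seq[alen:bstart])
        + rot.seq[bstart:]
    )
    return GenomeProduct(
        pair.pair_id, "inverted",
        [CircularGenome(f"{pair.pair_id}|isomer", inverted)],
    )


def fuse_products(p1: CircularGenome, p2: CircularGenome, repeat_len: int) -> CircularGenome:
    """Re-recombine two subgenomic circles at their shared leading repeat.

    Both products of a direct-repeat split begin with the shared repeat copy;
    fusing them regenerates a rotation of the parent circle.
    """
    if p1.seq[:repeat_len] != p2.seq[:repeat_len]:
        raise ValueError("products do not share a leading repeat copy")
    return CircularGenome(f"{p1.id}+{p2.id}", p1.seq + p2.seq)


def assessability(pair: RepeatPair, read_len: int = 150, insert_size: int = 300,
                  min_anchor: int = 25) -> tuple[bool, str]:
    """Can short paired-end reads discriminate this pair's conformations?

    A read pair is informative only if it bridges both flank-repeat junctions
    with at least ``min_anchor`` aligned bases beyond each; that requires
    ``repeat_length <= insert_size - 2*min_anchor``.  Repeats near or beyond
    the insert size (e.g. a ~16 kb repeat at a 300 bp insert) are flagged
    unassessable -- such cases need long-range methods instead.
    """
    limit = insert_size - 2 * min_anchor
    if pair.repeat_length <= limit:
        return True, (
            f"repeat {pair.repeat_length} bp <= {limit} bp "
            f"(insert {insert_size} - 2x{min_anchor} anchors)"
        )
    return False, (
        f"short-read-unassessable: repeat {pair.repeat_length} bp exceeds "
        f"{limit} bp (insert {insert_size} - 2x{min_anchor} anchors)"
    )
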