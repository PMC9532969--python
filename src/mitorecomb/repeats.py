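"""Maximal exact repeat detection on circular genomes.

Finds every repeated substring of length >= ``min_len`` in both orientations
and classifies copy pairs as direct (same strand) or inverted (opposite
strands).  Detection is exact: a reported unit is a literal maximal exact
repeat -- none of its copy sets can be extended left or right while all copies
still match.  The algorithm is k-mer seeding (k = min(31, min_len)) over the
circular sequence with bidirectional maximal extension and deduplication by
canonical coordinates; circularity is honoured, so repeats straddling the
linearization origin are found with wrap-aware coordinates.

The raw product, :func:`maximal_pair_matches`, is the set of maximal pairwise
matches; :func:`find_repeats` groups match copies that share the same
canonical sequence into units named R1, R2, ... by descending length.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .sequence_io import CircularGenome, revcomp

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class Match(NamedTuple):
    """One maximal pairwise exact match between two genomic windows.

    ``start1 <= start2`` (wrap-aware starts in ``[0, L)``); for an inverted
    match the window at ``start2`` equals the reverse complement of the window
    at ``start1``.  A palindromic self-match has ``start1 == start2``.
    """

    start1: int
    start2: int
    length: int
    orientation: str  # "direct" | "inverted"


@dataclass(frozen=True)
class RepeatCopy:
    """One genomic copy of a repeat unit.

    ``start`` is in ``[0, L)``; ``end = start + length`` may exceed the genome
    length for a copy wrapping through the origin.  ``strand`` is relative to
    the unit's canonical sequence: extracting this window on the stated strand
    yields that sequence exactly.
    """

    unit_id: str
    start: int
    end: int
    strand: str
    label: str = "a"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatUnit:
    unit_id: str
    length: int
    sequence: str  # canonical (lexicographic min of forward and revcomp)
    copies: list[RepeatCopy] = field(default_factory=list)

    @property
    def copy_count(self) -> int:
        return len(self.copies)


@dataclass
class RepeatPair:
    """Two copies of one unit plus orientation and overlap annotation."""

    pair_id: str
    unit_id: str
    copy_a: RepeatCopy
    copy_b: RepeatCopy
    orientation: str  # "direct" | "inverted"
    overlap_bp: int = 0
    overlap_partner: str | None = None
    assessable_by_short_reads: bool | None = None

    @property
    def repeat_length(self) -> int:
        return self.copy_a.length

    def swapped(self) -> "RepeatPair":
        """The same pair with the copy labels exchanged (for symmetry checks)."""
        return RepeatPair(
            self.pair_id, self.unit_id, self.copy_b, self.copy_a,
            self.orientation, self.overlap_bp, self.overlap_partner,
            self.assessable_by_short_reads,
        )


def _interval_segments(start: int, end: int, L: int) -> list[tuple[int, int]]:
    """A wrap-aware interval as one or two linear [s, e) segments in [0, L)."""
    if end <= L:
        return [(start, end)]
    return [(start, L), (0, end - L)]


def circular_overlap(c1: RepeatCopy, c2: RepeatCopy, L: int) -> int:
    """Number of genomic bases shared by two wrap-aware intervals."""
    total = 0
    for s1, e1 in _interval_segments(c1.start, c1.end, L):
        for s2, e2 in _interval_segments(c2.start, c2.end, L):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def maximal_pair_matches(genome: CircularGenome, min_len: int = 30) -> set[Match]:
    """All maximal pairwise exact matches of length >= ``min_len``.

    Both orientations are scanned.  ``N`` never matches (not even another
    ``N``), so runs of ambiguity break repeats.  Match length is capped at the
    genome length (relevant only for fully periodic circles).
    """
    if min_len < 8:
        raise ValueError("min_len < 8: seeding degenerates, refusing")
    L = genome.length
    if L < 2 * min_len:
        raise ValueError(f"genome length {L} < 2*min_len ({2 * min_len})")
    s = genome.seq
    if set(s) <= {"N"}:
        logger.warning("genome %r is all-N; no repeats reported", genome.id)
        return set()
    k = min(31, min_len)
    d = s + s

    buckets: dict[str, list[int]] = {}
    for i in range(L):
        km = d[i : i + k]
        if "N" in km:
            continue
        buckets.setdefault(km, []).append(i)

    matches: set[Match] = set()
    seen: set[tuple[str, int, int]] = set()

    def mark_direct(a: int, b: int, length: int) -> None:
        for t in range(min(length - k, L - 1) + 1):
            p1, p2 = (a + t) % L, (b + t) % L
            seen.add(("D", min(p1, p2), max(p1, p2)))

    def mark_inverted(a: int, b: int, length: int) -> None:
        for t in range(min(length - k, L - 1) + 1):
            p1 = (a + t) % L
            p2 = (b + length - k - t) % L
            seen.add(("I", min(p1, p2), max(p1, p2)))

    def extend_direct(i: int, j: int) -> tuple[int, int, int]:
        length = k
        while length < L:
            ci, cj = s[(i + length) % L], s[(j + length) % L]
            if ci != cj or ci == "N":
                break
            length += 1
        back = 0
        while length + back < L:
            ci, cj = s[(i - 1 - back) % L], s[(j - 1 - back) % L]
            if ci != cj or ci == "N":
                break
            back += 1
        return (i - back) % L, (j - back) % L, length + back

    def extend_inverted(ia: int, ja: int) -> tuple[int, int, int]:
        # invariant: window(ia, l, '+') == revcomp(window(ja, l, '+'))
        length = k
        while length < L:
            ci = s[(ia + length) % L]
            cj = s[(ja - 1) % L]
            if ci == "N" or ci != _COMP[cj]:
                break
            ja -= 1
            length += 1
        while length < L:
            ci = s[(ia - 1) % L]
            cj = s[(ja + length) % L]
            if ci == "N" or ci != _COMP[cj]:
                break
            ia -= 1
            length += 1
        return ia % L, ja % L, length

    # --- direct matches ---
    for pos in buckets.values():
        if len(pos) < 2:
            continue
        for i, j in itertools.combinations(pos, 2):
            key = ("D", i, j)
            if key in seen:
                continue
            a, b, length = extend_direct(i, j)
            if length >= min_len:
                mark_direct(a, b, length)
                lo, hi = sorted(((a % L), (b % L)))
                matches.add(Match(lo, hi, length, "direct"))
            else:
                seen.add(key)

    # --- inverted matches ---
    for km, pos in buckets.items():
        rc = revcomp(km)
        partners = buckets.get(rc)
        if not partners:
            continue
        for i in pos:
            for j in partners:
                # seed: window(i,k,'+') == revcomp(window(j,k,'+'))
                key = ("I", min(i, j), max(i, j))
                if key in seen:
                    continue
                a, b, length = extend_inverted(i, j)
                if length >= min_len:
                    mark_inverted(a, b, length)
                    lo, hi = sorted((a, b))
                    matches.add(Match(lo, hi, length, "inverted"))
                else:
                    seen.add(key)
    return matches


_LABELS = string.ascii_lowercase


def find_repeats(genome: CircularGenome, min_len: int = 30) -> list[RepeatUnit]:
    """Group maximal matches into repeat units with all their copies.

    Units are named R1, R2, ... by descending length, ties broken by leftmost
    copy start.  Copy strands are expressed relative to the unit's canonical
    sequence (lexicographic minimum of forward and reverse-complement).  A
    palindromic self-match is reported as a single unit whose two copies share
    coordinates on opposite strands.
    """
    matches = maximal_pair_matches(genome, min_len)
    groups: dict[str, set[tuple[int, int, str]]] = {}
    for m in matches:
        if m.orientation == "inverted" and m.start1 == m.start2:
            fwd = genome.window(m.start1, m.length, "+")
            can = min(fwd, revcomp(fwd))
            grp = groups.setdefault(can, set())
            grp.add((m.start1, m.length, "+"))
            grp.add((m.start1, m.length, "-"))
            continue
        for start in (m.start1, m.start2):
            fwd = genome.window(start, m.length, "+")
            can = min(fwd, revcomp(fwd))
            strand = "+" if fwd == can else "-"
            groups.setdefault(can, set()).add((start, m.length, strand))

    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[0]), min(c[0] for c in kv[1]))
    )
    units = []
    for idx, (can, copyset) in enumerate(ordered, start=1):
        uid = f"R{idx}"
        copies = [
            RepeatCopy(uid, start, start + length, strand, _LABELS[i % 26])
            for i, (start, length, strand) in enumerate(sorted(copyset))
        ]
        units.append(RepeatUnit(uid, len(can), can, copies))
    return units


def classify_pairs(units: Iterable[RepeatUnit], genome_length: int) -> list[RepeatPair]:
    """All unordered copy pairs per unit, classified and overlap-annotated.

    A pair is *direct* when both copies sit on the same strand relative to the
    canonical unit sequence and *inverted* otherwise.  ``overlap_bp`` records
    genomic bases shared with a copy of a different unit (the shared-copy
    special case); a palindromic unit overlaps itself over its full length.
    """
    pairs: list[RepeatPair] = []
    for unit in units:
        combos = list(itertools.combinations(unit.copies, 2))
        for a, b in combos:
            if len(combos) == 1:
                pid = unit.unit_id
            else:
                pid = f"{unit.unit_id}_{a.label}{b.label}"
            if (a.start, a.end) == (b.start, b.end) and a.strand != b.strand:
                pairs.append(
                    RepeatPair(pid, unit.unit_id, a, b, "inverted",
                               overlap_bp=a.length, overlap_partner=pid)
                )
                continue
            orientation = "direct" if a.strand == b.strand else "inverted"
            pairs.append(RepeatPair(pid, unit.unit_id, a, b, orientation))

    for p in pairs:
        for q in pairs:
            if p.unit_id == q.unit_id:
                continue
            ov = max(
                circular_overlap(cp, cq, genome_length)
                for cp in (p.copy_a, p.copy_b)
                for cq in (q.copy_a, q.copy_b)
            )
            if ov > p.overlap_bp:
                p.overlap_bp = ov
                p.overlap_partner = q.pair_id
    return pairs


def repeat_summary(genome: CircularGenome, units: Iterable[RepeatUnit]) -> dict:
    """Genome-wide summary: unit/copy counts, repetitive bases and GC.

    ``repetitive_bp`` is the size of the union of all copy intervals -- a base
    lying in several copies is counted once.
    """
    L = genome.length
    covered = np.zeros(L, dtype=bool)
    n_units = 0
    n_copies = 0
    for unit in units:
        n_units += 1
        for c in unit.copies:
            n_copies += 1
            for s, e in _interval_segments(c.start, c.end, L):
                covered[s:e] = True
    repetitive = int(covered.sum())
    return {
        "n_units": n_units,
        "n_copies": n_copies,
        "repetitive_bp": repetitive,
        "repeat_fraction": repetitive / L,
        "gc_content": genome.gc_content(),
        "genome_length": L,
    }
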