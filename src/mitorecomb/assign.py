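"""Assignment of read pairs to conformation members.

The engine is a deterministic gapless local aligner: k-mer seeds anchor a
read at candidate diagonals on each conformation member (and on any decoy
sequences), and the best-scoring contiguous segment on each diagonal is found
by a vectorised maximum-subarray scan (+1 match, -4 mismatch).  A read pair
supports a member only when

1. its best-scoring placement is on that member, strictly better than on any
   other member and any decoy;
2. each mate's aligned length reaches ``min_aln`` (default 100 bp -- the
   filter that suppresses short nuclear-homology alignments);
3. the pair is discriminative: jointly its mates cover both flank-repeat
   junctions with at least ``min_anchor`` aligned bases beyond each junction
   into flank sequence.

Ties across members are never broken by chance; they are counted as
ambiguous.  Contaminant pairs whose best placement is a decoy (e.g. the
plastid genome) are tallied separately and never touch the support counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .conformations import REFERENCE, RECOMBINED, Conformation, ConformationSet
from .sequence_io import CircularGenome, ReadPair, revcomp

_N = ord("N")


@dataclass
class AssignmentCounts:
    """Disjoint tallies of read-pair fates for one repeat pair.

    ``member_counts`` generalises the four classic counters to the 3+3
    overlap case; ``Naa``/``Nbb``/``Nab``/``Nba`` views are provided for the
    standard four-member sets.
    """

    pair_id: str
    member_counts: dict[str, int]
    member_kinds: dict[str, str]
    n_ambiguous: int = 0
    n_filtered_short: int = 0
    n_filtered_decoy: int = 0
    n_unmapped: int = 0

    @classmethod
    def from_quad(cls, pair_id: str, naa: int, nbb: int, nab: int, nba: int
                  ) -> "AssignmentCounts":
        return cls(
            pair_id,
            {"aa": naa, "bb": nbb, "ab": nab, "ba": nba},
            {"aa": REFERENCE, "bb": REFERENCE, "ab": RECOMBINED, "ba": RECOMBINED},
        )

    @classmethod
    def from_totals(cls, pair_id: str, n_ref: int, n_rec: int) -> "AssignmentCounts":
        """Summed reference/recombined support (the overlap-pair reporting form)."""
        return cls(
            pair_id,
            {"ref": n_ref, "rec": n_rec},
            {"ref": REFERENCE, "rec": RECOMBINED},
        )

    def _get(self, label: str) -> int:
        return self.member_counts.get(label, 0)

    @property
    def Naa(self) -> int:
        return self._get("aa")

    @property
    def Nbb(self) -> int:
        return self._get("bb")

    @property
    def Nab(self) -> int:
        return self._get("ab")

    @property
    def Nba(self) -> int:
        return self._get("ba")

    @property
    def n_ref(self) -> int:
        return sum(c for m, c in self.member_counts.items()
                   if self.member_kinds[m] == REFERENCE)

    @property
    def n_rec(self) -> int:
        return sum(c for m, c in self.member_counts.items()
                   if self.member_kinds[m] == RECOMBINED)

    @property
    def n_assigned(self) -> int:
        return sum(self.member_counts.values())


@dataclass
class _Alignment:
    score: int
    start: int  # on the reference, 0-based
    end: int
    mismatches: int

    @property
    def aligned_len(self) -> int:
        return self.end - self.start


class _RefIndex:
    """Seeded byte-array view of one reference sequence."""

    MATCH = 1
    MISMATCH_PENALTY = 4

    def __init__(self, name: str, seq: str, seed_k: int = 15,
                 circular: bool = False):
        self.name = name
        self.true_len = len(seq)
        if circular:
            seq = seq + seq[: min(400, len(seq))]
        self.arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self.seed_k = seed_k
        self.kmers: dict[bytes, list[int]] = {}
        raw = seq.encode()
        for i in range(len(raw) - seed_k + 1):
            km = raw[i : i + seed_k]
            self.kmers.setdefault(km, []).append(i)

    def align(self, read: np.ndarray, raw: bytes,
              max_mismatch_rate: float) -> _Alignment | None:
        k = self.seed_k
        n = len(read)
        if n < k:
            return None
        offsets: set[int] = set()
        for p in (0, (n - k) // 2, n - k):
            for h in self.kmers.get(raw[p : p + k], ()):
                offsets.add(h - p)
        best: _Alignment | None = None
        M = len(self.arr)
        for off in sorted(offsets):
            s = max(0, off)
            e = min(M, off + n)
            if e - s < k:
                continue
            ref_seg = self.arr[s:e]
            read_seg = read[s - off : e - off]
            eq = (ref_seg == read_seg) & (ref_seg != _N)
            vals = np.where(eq, self.MATCH, -self.MISMATCH_PENALTY)
            # best local (maximum-subarray) segment on this diagonal
            c = np.concatenate(([0], np.cumsum(vals)))
            pre_min = np.minimum.accumulate(c[:-1])
            gains = c[1:] - pre_min
            ei = int(np.argmax(gains))
            score = int(gains[ei])
            if score <= 0:
                continue
            si = int(np.flatnonzero(c[: ei + 1] == pre_min[ei])[0])
            seg_len = ei + 1 - si
            mm = seg_len - int(eq[si : ei + 1].sum())
            if mm > max_mismatch_rate * seg_len:
                continue
            cand = _Alignment(score, s + si, s + ei + 1, mm)
            if best is None or cand.score > best.score:
                best = cand
        return best


def _pair_alignment(index: _RefIndex, m1f, m1r, m2f, m2r, max_mm):
    """Best FR-oriented placement of a pair on one reference.

    Returns (total score, list of per-mate alignments or None).  Orientation
    configurations: mate1 forward + mate2 reverse-complemented, or vice
    versa; an unaligned mate contributes nothing to the score.
    """
    best_score = None
    best = None
    for a_arr, a_raw, b_arr, b_raw in (
        (m1f[0], m1f[1], m2r[0], m2r[1]),
        (m1r[0], m1r[1], m2f[0], m2f[1]),
    ):
        al_a = index.align(a_arr, a_raw, max_mm)
        al_b = index.align(b_arr, b_raw, max_mm)
        if al_a is None and al_b is None:
            continue
        score = (al_a.score if al_a else 0) + (al_b.score if al_b else 0)
        if best_score is None or score > best_score:
            best_score = score
            best = [al_a, al_b]
    return best_score, best


def _encode(seq: str) -> tuple[np.ndarray, bytes]:
    raw = seq.encode()
    return np.frombuffer(raw, dtype=np.uint8), raw


def assign_read_pairs(
    reads: Iterable[ReadPair],
    confs: ConformationSet,
    decoys: Sequence[CircularGenome] = (),
    min_aln: int = 100,
    min_anchor: int = 25,
    max_mismatch_rate: float = 0.02,
    seed_k: int = 15,
) -> AssignmentCounts:
    """Assign read pairs to the members of one conformation set.

    See the module docstring for the support rule.  Counters are disjoint:
    every input pair increments exactly one of the member counters,
    ``n_ambiguous``, ``n_filtered_short``, ``n_filtered_decoy`` or
    ``n_unmapped``.
    """
    members = confs.members
    shortest = min(len(m.sequence) for m in members)
    indexes = [(m, _RefIndex(m.label, m.sequence, seed_k)) for m in members]
    decoy_indexes = [
        _RefIndex(d.id, d.seq, seed_k, circular=d.circular) for d in decoys
    ]

    counts = AssignmentCounts(
        confs.pair_id,
        {m.label: 0 for m in members},
        {m.label: m.kind for m in members},
    )

    for pair in reads:
        if len(pair.mate1) > shortest or len(pair.mate2) > shortest:
            raise ValueError(
                "read longer than a conformation member; rebuild with a "
                "larger flank_len"
            )
        m1f = _encode(pair.mate1)
        m1r = _encode(revcomp(pair.mate1))
        m2f = _encode(pair.mate2)
        m2r = _encode(revcomp(pair.mate2))

        scored: list[tuple[int, Conformation, list]] = []
        for member, idx in indexes:
            score, als = _pair_alignment(idx, m1f, m1r, m2f, m2r,
                                         max_mismatch_rate)
            if score is not None:
                scored.append((score, member, als))
        decoy_best = None
        for didx in decoy_indexes:
            score, _ = _pair_alignment(didx, m1f, m1r, m2f, m2r,
                                       max_mismatch_rate)
            if score is not None and (decoy_best is None or score > decoy_best):
                decoy_best = score

        if not scored and decoy_best is None:
            counts.n_unmapped += 1
            continue
        if decoy_best is not None and (
            not scored or decoy_best >= max(s for s, _, _ in scored)
        ):
            counts.n_filtered_decoy += 1
            continue

        scored.sort(key=lambda t: t[0], reverse=True)
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            counts.n_ambiguous += 1
            continue
        _, member, als = scored[0]
        if any(a is None or a.aligned_len < min_aln for a in als):
            counts.n_filtered_short += 1
            continue
        lj, rj = member.left_junction, member.right_junction
        ivs = [(a.start, a.end) for a in als]

        def jointly_covered(lo: int, hi: int) -> bool:
            # every base in [lo, hi) lies in some mate's aligned interval
            pos = lo
            for s, e in sorted(ivs):
                if s > pos:
                    return False
                pos = max(pos, e)
                if pos >= hi:
                    return True
            return pos >= hi

        cover_left = jointly_covered(lj - min_anchor, lj + 1)
        cover_right = jointly_covered(rj - 1, rj + min_anchor)
        if not (cover_left and cover_right):
            counts.n_ambiguous += 1
            continue
        counts.member_counts[member.label] += 1
    return counts
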