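"""Independent brute-force oracles used only by the tests.

The repeat-finder oracle compares the circular sequence against every
rotation of itself (direct matches) and of its reverse complement (inverted
matches) and extracts maximal equality runs.  This is an all-substring-pairs
scan organised by shift, with no shared machinery (no k-mer seeding, no
extension) with the package's finder.
"""

from __future__ import annotations

import numpy as np

from mitorecomb.repeats import Match, _interval_segments
from mitorecomb.sequence_io import CircularGenome, revcomp

_N = ord("N")


def _circular_runs(eq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array as (start, length)."""
    L = len(eq)
    if eq.all():
        return [(0, L)]
    falses = np.flatnonzero(~eq)
    runs = []
    for idx in range(len(falses)):
        a = int(falses[idx])
        b = int(falses[(idx + 1) % len(falses)]) + (L if idx + 1 == len(falses) else 0)
        gap = b - a - 1
        if gap > 0:
            runs.append(((a + 1) % L, gap))
    return runs


def _has_long_run(eq: np.ndarray, min_len: int) -> bool:
    """Cheap necessary test: a True run >= min_len contains an aligned block."""
    b = max(1, min_len // 2)
    ext = np.concatenate([eq, eq[: 2 * b]])
    n = (len(ext) // b) * b
    return bool(ext[:n].reshape(-1, b).all(axis=1).any())


def brute_force_matches(genome: CircularGenome, min_len: int = 30) -> set[Match]:
    """All maximal pairwise exact matches >= min_len, by exhaustive shift scan."""
    L = genome.length
    s = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    matches: set[Match] = set()

    for d in range(1, L):
        eq = (s == np.roll(s, -d)) & (s != _N)
        if not _has_long_run(eq, min_len):
            continue
        for start, ln in _circular_runs(eq):
            if ln < min_len:
                continue
            p1, p2 = start, (start + d) % L
            lo, hi = sorted((p1, p2))
            matches.add(Match(lo, hi, min(ln, L), "direct"))

    h = np.frombuffer(revcomp(genome.seq).encode(), dtype=np.uint8)
    for d in range(L):
        hr = np.roll(h, -d)
        eq = (s == hr) & (s != _N)
        if not _has_long_run(eq, min_len):
            continue
        for start, ln in _circular_runs(eq):
            if ln < min_len:
                continue
            ln = min(ln, L)
            y0 = (start + d) % L
            g2 = (L - y0 - ln) % L
            lo, hi = sorted((start, g2))
            matches.add(Match(lo, hi, ln, "inverted"))
    return matches


def per_base_copy_depth(genome: CircularGenome, units) -> np.ndarray:
    """How many repeat copies cover each genomic base (summary oracle)."""
    depth = np.zeros(genome.length, dtype=int)
    for u in units:
        for c in u.copies:
            for a, b in _interval_segments(c.start, c.end, genome.length):
                depth[a:b] += 1
    return depth
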