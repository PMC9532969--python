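import numpy as np
import pytest

from _oracle import brute_force_matches, per_base_copy_depth
from conftest import plant, random_seq
from mitorecomb import (
    CircularGenome,
    classify_pairs,
    find_repeats,
    maximal_pair_matches,
    repeat_summary,
    revcomp,
)
from mitorecomb.repeats import Match


def _match_set_rotated(matches, k, L):
    """Shift a match set by a rotation of k (origin moved to position k)."""
    out = set()
    for m in matches:
        p1, p2 = (m.start1 - k) % L, (m.start2 - k) % L
        lo, hi = sorted((p1, p2))
        out.add(Match(lo, hi, m.length, m.orientation))
    return out


class TestFindRepeats:
    def test_no_repeats_in_clean_background(self, rng):
        for _ in range(5):
            g = CircularGenome("g", random_seq(rng, 500))
            if not brute_force_matches(g, 30):
                assert find_repeats(g, 30) == []
                return
        pytest.fail("could not draw a repeat-free background")

    def test_planted_direct_pair(self, rng):
        R = random_seq(rng, 150)
        g = plant(rng, 2000, [("bg", 300), ("seq", R), ("bg", 600),
                              ("seq", R), ("bg", 800)])
        units = find_repeats(g, 30)
        assert len(units) == 1
        (u,) = units
        assert u.length == 150 and u.copy_count == 2
        # direct pair: both copies on the same strand relative to canonical
        assert len({c.strand for c in u.copies}) == 1
        assert sorted(c.start for c in u.copies) == [300, 1050]
        assert maximal_pair_matches(g, 30) == brute_force_matches(g, 30)

    def test_planted_inverted_pair(self, rng):
        R = random_seq(rng, 150)
        g = plant(rng, 2000, [("bg", 300), ("seq", R), ("bg", 600),
                              ("seq", revcomp(R)), ("bg", 800)])
        units = find_repeats(g, 30)
        assert len(units) == 1
        (u,) = units
        assert sorted(c.strand for c in u.copies) == ["+", "-"]
        assert maximal_pair_matches(g, 30) == brute_force_matches(g, 30)

    def test_repeat_straddling_origin(self, rng):
        R = random_seq(rng, 150)
        g = plant(rng, 2000, [("bg", 300), ("seq", R), ("bg", 600),
                              ("seq", R), ("bg", 800)])
        base = maximal_pair_matches(g, 30)
        k = 380  # origin lands inside the first copy
        rot = g.rotated(k)
        assert maximal_pair_matches(rot, 30) == _match_set_rotated(
            base, k, g.length
        )
        # and a wrapped copy is reported wrap-aware
        units = find_repeats(rot, 30)
        wrapped = [c for u in units for c in u.copies if c.end > rot.length]
        assert wrapped and all(
            rot.window(c.start, c.length, c.strand) == u.sequence
            for u in units for c in u.copies
        )

    def test_rotation_invariance_random(self, rng):
        R = random_seq(rng, 80)
        g = plant(rng, 1500, [("bg", 200), ("seq", R), ("bg", 500),
                              ("seq", revcomp(R)), ("bg", 640)])
        base = maximal_pair_matches(g, 30)
        for k in (1, 137, 999):
            assert maximal_pair_matches(g.rotated(k), 30) == \
                _match_set_rotated(base, k, g.length)

    def test_strand_symmetry(self, rng):
        R = random_seq(rng, 90)
        g = plant(rng, 1500, [("bg", 200), ("seq", R), ("bg", 500),
                              ("seq", R), ("bg", 620)])
        fwd_units = find_repeats(g, 30)
        rc_units = find_repeats(CircularGenome("rc", revcomp(g.seq)), 30)
        assert len(fwd_units) == len(rc_units)
        for u1, u2 in zip(fwd_units, rc_units):
            assert u1.length == u2.length
            assert u1.sequence == u2.sequence  # canonical form is strand-free

    def test_min_len_monotonicity(self, rng):
        R = random_seq(rng, 60)
        g = plant(rng, 1200, [("bg", 200), ("seq", R), ("bg", 400),
                              ("seq", R), ("bg", 480)])
        long_units = {u.sequence for u in find_repeats(g, 50)}
        short_units = {u.sequence for u in find_repeats(g, 30)}
        assert long_units <= short_units

    def test_min_len_too_small_refused(self, rng):
        g = CircularGenome("g", random_seq(rng, 200))
        with pytest.raises(ValueError):
            find_repeats(g, 7)

    def test_all_n_genome_empty(self, caplog):
        g = CircularGenome("g", "N" * 200)
        assert find_repeats(g, 30) == []

    def test_three_copy_unit_yields_three_pairs(self, rng):
        R = random_seq(rng, 100)
        g = plant(rng, 2400, [("bg", 200), ("seq", R), ("bg", 400),
                              ("seq", R), ("bg", 400), ("seq", R),
                              ("bg", 1100)])
        units = find_repeats(g, 30)
        assert len(units) == 1 and units[0].copy_count == 3
        pairs = classify_pairs(units, g.length)
        assert len(pairs) == 3
        assert all(p.orientation == "direct" for p in pairs)


class TestClassifyPairs:
    def test_direct_vs_inverted(self, direct_toy, inverted_toy):
        for fixture, expected in ((direct_toy, "direct"),
                                  (inverted_toy, "inverted")):
            g = fixture[0]
            pairs = classify_pairs(find_repeats(g, 30), g.length)
            assert len(pairs) == 1
            assert pairs[0].orientation == expected

    def test_overlapping_units_annotated(self, rng):
        # unit X (60 bp) and unit Y (60 bp) share 3 bp in one copy
        X = random_seq(rng, 60)
        Y = X[-3:] + random_seq(rng, 57)
        g = plant(rng, 3000, [
            ("bg", 200), ("seq", X), ("bg", 500),
            ("seq", X), ("seq", Y[3:]),  # Y's copy overlaps X's by 3 bp
            ("bg", 500), ("seq", Y), ("bg", 1563),
        ])
        pairs = classify_pairs(find_repeats(g, 30), g.length)
        assert len(pairs) == 2
        by_len = sorted(pairs, key=lambda p: p.repeat_length)
        assert all(p.overlap_bp == 3 for p in pairs)
        assert pairs[0].overlap_partner == pairs[1].pair_id
        assert pairs[1].overlap_partner == pairs[0].pair_id


class TestSummary:
    def test_zero_repeats(self, rng):
        g = CircularGenome("g", random_seq(rng, 500))
        units = find_repeats(g, 30)
        if units:
            pytest.skip("accidental repeat in draw")
        s = repeat_summary(g, units)
        assert s["repetitive_bp"] == 0 and s["repeat_fraction"] == 0

    def test_gc_of_symmetric_composition(self):
        assert CircularGenome("g", "ATGC").gc_content() == 0.5
        s = repeat_summary(CircularGenome("g", "ATGC" * 20), [])
        assert s["gc_content"] == 0.5

    def test_union_matches_per_base_oracle(self, rng):
        R = random_seq(rng, 100)
        S = random_seq(rng, 50)
        g = plant(rng, 2500, [("bg", 100), ("seq", R), ("bg", 300),
                              ("seq", R), ("bg", 300), ("seq", S),
                              ("bg", 400), ("seq", revcomp(S)), ("bg", 1100)])
        units = find_repeats(g, 30)
        s = repeat_summary(g, units)
        depth = per_base_copy_depth(g, units)
        assert s["repetitive_bp"] == int((depth > 0).sum())
        assert s["n_copies"] == sum(u.copy_count for u in units)
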