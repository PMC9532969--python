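import numpy as np
import pytest

from conftest import plant, random_seq
from mitorecomb import (
    CircularGenome,
    assessability,
    build_conformations,
    build_overlap_conformations,
    classify_pairs,
    find_repeats,
    fuse_products,
    recombine_genome,
    revcomp,
)
from mitorecomb.conformations import FlankError
from mitorecomb.repeats import RepeatCopy, RepeatPair


def _pair_of(genome, min_len=30):
    pairs = classify_pairs(find_repeats(genome, min_len), genome.length)
    assert len(pairs) == 1
    return pairs[0]


class TestBuildConformations:
    def test_direct_members_hand_assembled(self, direct_toy):
        g, R, (sa, ea), (sb, eb) = direct_toy
        S, D = g.seq, g.seq + g.seq
        la = D[(sa - 300) % 1200 : (sa - 300) % 1200 + 300]
        ra = S[ea : ea + 300]
        lb = S[sb - 300 : sb]
        rb = S[eb : eb + 300]
        confs = build_conformations(g, _pair_of(g), 300)
        assert confs["aa"].sequence == la + R + ra
        assert confs["bb"].sequence == lb + R + rb
        assert confs["ab"].sequence == la + R + rb
        assert confs["ba"].sequence == lb + R + ra
        for m in confs.members:
            assert (m.left_junction, m.right_junction) == (300, 420)

    def test_inverted_ab_uses_revcomp_of_b_left_flank(self, inverted_toy):
        g, R, (sa, ea), (sb, eb) = inverted_toy
        S, D = g.seq, g.seq + g.seq
        la = D[(sa - 300) % 1200 : (sa - 300) % 1200 + 300]
        left_flank_b_genomic = S[sb - 300 : sb]
        confs = build_conformations(g, _pair_of(g), 300)
        assert confs["ab"].sequence == la + R + revcomp(left_flank_b_genomic)

    def test_zero_flank_is_degenerate(self, direct_toy):
        g, R, *_ = direct_toy
        confs = build_conformations(g, _pair_of(g), 0)
        assert confs.degenerate
        assert all(m.sequence == R for m in confs.members)

    def test_member_lengths_and_junctions(self, direct_toy):
        g, R, *_ = direct_toy
        confs = build_conformations(g, _pair_of(g), 150)
        for m in confs.members:
            assert len(m.sequence) == 150 + len(R) + 150
            assert m.sequence[m.left_junction : m.right_junction] == R

    def test_flank_truncated_at_neighbouring_copy(self, direct_toy):
        g, R, (sa, ea), (sb, eb) = direct_toy
        pair = _pair_of(g)
        # a foreign repeat copy ending 80 bp left of copy_a (wrap-aware start)
        blocker = RepeatCopy("X", (sa - 300) % 1200, (sa - 300) % 1200 + 220, "+")
        confs = build_conformations(
            g, pair, 300, all_copies=[pair.copy_a, pair.copy_b, blocker]
        )
        assert confs["aa"].truncated_left == 300 - 80
        assert confs["aa"].left_junction == 80
        assert confs["bb"].truncated_left == 0

    def test_fully_blocked_flanks_rejected(self, direct_toy):
        g, R, (sa, ea), (sb, eb) = direct_toy
        pair = _pair_of(g)
        blockers = [
            RepeatCopy("X", sb - 300, sb, "+"),
            RepeatCopy("Y", eb % 1200, eb + 300, "+"),
        ]
        with pytest.raises(FlankError):
            build_conformations(
                g, pair, 300,
                all_copies=[pair.copy_a, pair.copy_b, *blockers],
            )

    def test_flank_exchange_is_an_involution(self, direct_toy):
        """ab/ba are aa/bb with right flanks exchanged; exchanging twice
        restores the reference members."""
        g, R, *_ = direct_toy
        confs = build_conformations(g, _pair_of(g), 300)
        aa, bb, ab, ba = (confs[k] for k in ("aa", "bb", "ab", "ba"))

        def right(m):
            return m.sequence[m.right_junction :]

        def core(m):
            return m.sequence[: m.right_junction]

        assert ab.sequence == core(aa) + right(bb)
        assert ba.sequence == core(bb) + right(aa)
        assert core(ab) + right(ba) == aa.sequence
        assert core(ba) + right(ab) == bb.sequence

    def test_recombined_members_mix_flanks(self, inverted_toy):
        g, *_ = inverted_toy
        confs = build_conformations(g, _pair_of(g), 300)
        aa, bb = confs["aa"], confs["bb"]
        la, ra = aa.sequence[:300], aa.sequence[-300:]
        lb, rb = bb.sequence[:300], bb.sequence[-300:]
        for m in confs.recombined_members:
            left, rgt = m.sequence[:300], m.sequence[-300:]
            assert (left == la and rgt == rb) or (left == lb and rgt == ra)
        for m in confs.reference_members:
            left, rgt = m.sequence[:300], m.sequence[-300:]
            assert (left, rgt) in {(la, ra), (lb, rb)}


class TestOverlapConformations:
    @pytest.fixture
    def overlap_fixture(self, rng):
        X = random_seq(rng, 60)
        Y = X[-3:] + random_seq(rng, 57)
        g = plant(rng, 3000, [
            ("bg", 200), ("seq", X), ("bg", 500),
            ("seq", X), ("seq", Y[3:]),
            ("bg", 500), ("seq", Y), ("bg", 1563),
        ])
        pairs = classify_pairs(find_repeats(g, 30), g.length)
        assert len(pairs) == 2 and all(p.overlap_bp == 3 for p in pairs)
        return g, pairs

    def test_three_plus_three_members(self, overlap_fixture):
        g, (p1, p2) = overlap_fixture
        s1, s2 = build_overlap_conformations(g, p1, p2, 300)
        for cs in (s1, s2):
            assert len(cs.reference_members) == 3
            assert len(cs.recombined_members) == 3

    def test_members_pairwise_distinct(self, overlap_fixture):
        g, (p1, p2) = overlap_fixture
        s1, s2 = build_overlap_conformations(g, p1, p2, 300)
        for cs in (s1, s2):
            seqs = [m.sequence for m in cs.members]
            assert len(set(seqs)) == len(seqs)

    def test_zero_overlap_falls_back_to_two_plus_two(self, rng):
        X = random_seq(rng, 60)
        Y = random_seq(rng, 60)
        g = plant(rng, 3000, [
            ("bg", 200), ("seq", X), ("bg", 400), ("seq", X), ("bg", 400),
            ("seq", Y), ("bg", 400), ("seq", Y), ("bg", 1360),
        ])
        pairs = classify_pairs(find_repeats(g, 30), g.length)
        assert all(p.overlap_bp == 0 for p in pairs)
        s1, s2 = build_overlap_conformations(g, pairs[0], pairs[1], 300)
        for cs in (s1, s2):
            assert len(cs.members) == 4

    def test_full_copy_overlap_unsupported(self, rng):
        # partner copy nested entirely inside the shared copy
        g = CircularGenome("g", random_seq(rng, 2000))
        p1 = RepeatPair("P", "u1", RepeatCopy("u1", 100, 200, "+"),
                        RepeatCopy("u1", 500, 600, "+"), "direct",
                        overlap_bp=40, overlap_partner="Q")
        p2 = RepeatPair("Q", "u2", RepeatCopy("u2", 520, 560, "+"),
                        RepeatCopy("u2", 800, 840, "+"), "direct",
                        overlap_bp=40, overlap_partner="P")
        with pytest.raises(ValueError, match="entire copy"):
            build_overlap_conformations(g, p1, p2, 300)


class TestRecombineGenome:
    def test_direct_split_hand_layout(self, rng):
        # circle [A(500) R(100) B(300) R(100)]: products A+R (600), B+R (400)
        R = random_seq(rng, 100)
        g = plant(rng, 1000, [("bg", 500), ("seq", R), ("bg", 300), ("seq", R)])
        pair = _pair_of(g)
        prod = recombine_genome(g, pair)
        lengths = sorted(p.length for p in prod.products)
        assert lengths == [400, 600]
        assert sum(lengths) == g.length
        for p in prod.products:
            # exactly one circular occurrence of the repeat per product
            doubled = p.seq + p.seq
            hits = [i for i in range(p.length) if doubled[i : i + 100] == R]
            assert len(hits) == 1

    def test_direct_round_trip_regenerates_parent_rotation(self, direct_toy):
        g, R, *_ = direct_toy
        pair = _pair_of(g)
        p1, p2 = recombine_genome(g, pair).products
        fused = fuse_products(p1, p2, pair.repeat_length)
        assert fused.length == g.length
        assert fused.seq in g.seq + g.seq  # a rotation of the parent

    def test_inverted_product_conserves_length_and_pairing(self, inverted_toy):
        g, *_ = inverted_toy
        pair = _pair_of(g)
        (prod,) = recombine_genome(g, pair).products
        assert prod.length == g.length
        # double-strand base pairing is conserved: A+T and G+C totals
        def at_gc(s):
            return (s.count("A") + s.count("T"), s.count("G") + s.count("C"))
        assert at_gc(prod.seq) == at_gc(g.seq)

    def test_inverted_is_an_involution(self, inverted_toy):
        g, R, (sa, ea), (sb, eb) = inverted_toy
        pair = _pair_of(g)
        (prod,) = recombine_genome(g, pair).products
        # the product carries the same pair at frame-relative coordinates
        L = g.length
        pair2 = RepeatPair(
            "p2", "u", RepeatCopy("u", 0, ea - sa, "+"),
            RepeatCopy("u", (sb - sa) % L, (eb - sa) % L, "-"), "inverted",
        )
        (back,) = recombine_genome(prod, pair2).products
        assert back.seq == g.rotated(sa).seq

    def test_overlapping_copies_rejected(self, rng):
        a = RepeatCopy("u", 100, 200, "+")
        b = RepeatCopy("u", 150, 250, "+")
        pair = RepeatPair("p", "u", a, b, "direct")
        g = CircularGenome("g", random_seq(rng, 1000))
        with pytest.raises(ValueError, match="overlap"):
            recombine_genome(g, pair)


class TestAssessability:
    @pytest.mark.parametrize(
        "length,expected",
        [(16366, False), (111, True), (300, False), (250, True), (251, False)],
    )
    def test_insert_bridging_rule(self, length, expected):
        pair = RepeatPair(
            "p", "u", RepeatCopy("u", 0, length, "+"),
            RepeatCopy("u", 5000 + length, 5000 + 2 * length, "+"), "direct",
        )
        ok, reason = assessability(pair, read_len=150, insert_size=300,
                                   min_anchor=25)
        assert ok is expected
        if not ok:
            assert "unassessable" in reason
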