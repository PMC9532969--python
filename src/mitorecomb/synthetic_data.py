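"""Synthetic circular genomes and paired-end reads with known ground truth.

The generator emulates the study conditions the pipeline targets: a circular
mitochondrial-like genome (~43% GC) carrying planted exact repeat pairs, and
150 bp paired-end reads at a 300 bp mean insert drawn from a molecule
population mixing the reference circle with its recombination products at a
chosen molar fraction ``f``.  Because fragments are sampled uniformly per
base across the population, the expected fraction of junction-spanning read
pairs that support recombined conformations equals ``f`` -- the generator's
``recombined_fraction`` is directly the quantity the estimator recovers.

Contaminants can be mixed in to exercise the assignment filters: whole read
pairs from a plastid-like decoy circle, and "nuclear-like" chimeric reads
that share only a sub-``min_aln`` stretch of homology with the target locus.

All randomness flows from a single seed; equal configurations give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .conformations import assessability, recombine_genome
from .repeats import (
    Match,
    RepeatPair,
    classify_pairs,
    find_repeats,
    maximal_pair_matches,
)
from .sequence_io import CircularGenome, ReadPair, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedRepeat:
    """One repeat pair to plant: two copies of a ``length``-bp block.

    ``overlap_bp > 0`` makes the second copy of this unit share that many
    genomic bases with the second copy of the *previous* planted unit (the
    shared-copy special case).
    """

    length: int
    orientation: str = "direct"  # "direct" | "inverted"
    overlap_bp: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for genome and read simulation.

    Defaults follow the sequencing geometry the pipeline targets: 150 bp
    paired-end reads, 300 bp mean insert (sd 30), ~43% GC background.
    """

    genome_length: int = 10_000
    planted: tuple[PlantedRepeat, ...] = ()
    read_length: int = 150
    insert_mean: int = 300
    insert_sd: float = 30.0
    n_pairs: int = 5_000
    error_rate: float = 0.0
    recombined_fraction: float = 0.5
    decoy_fraction: float = 0.0
    nuclear_fraction: float = 0.0
    gc_content: float = 0.435
    min_repeat_len: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "recombined_fraction", "decoy_fraction",
                     "nuclear_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total_planted = sum(2 * p.length for p in self.planted)
        if self.planted and self.genome_length < 2 * total_planted:
            raise ValueError("genome_length < 4x total planted repeat length")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _place_copies(rng, L, lengths, margin):
    """Random non-wrapping start positions, pairwise separated by ``margin``."""
    for _ in range(200):
        starts = sorted(int(rng.integers(0, L)) for _ in lengths)
        order = rng.permutation(len(lengths))
        chosen = [(starts[i], int(lengths[order[i]]), int(order[i]))
                  for i in range(len(lengths))]
        ok = True
        for idx, (s1, l1, _) in enumerate(chosen):
            if s1 + l1 > L:  # planted copies never wrap; tests rotate instead
                ok = False
                break
            nxt = (idx + 1) % len(chosen)
            s2 = chosen[nxt][0] + (L if nxt == 0 else 0)
            if s2 - (s1 + l1) < margin:
                ok = False
                break
        if ok:
            return chosen
    return None


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CircularGenome, list[RepeatPair]]:
    """A random circular genome with exactly the planted repeat structure.

    The background is rejection-checked with the repeat finder: a draw is
    discarded if any maximal repeat >= ``min_repeat_len`` other than the
    planted ones appears (or if a planted one was corrupted by chance
    context).  Returns the genome and the ground-truth classified pairs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_length
    margin = 400  # room for 300 bp single-copy flanks plus slack

    for _attempt in range(30):
        bg = _random_bases(rng, L, config.gc_content)

        # draw unit sequences; an overlapping unit must start with the tail
        # of its predecessor so the shared bases are consistent
        unit_seqs: list[np.ndarray] = []
        for p in config.planted:
            seq = _random_bases(rng, p.length, config.gc_content)
            if p.overlap_bp > 0:
                if not unit_seqs:
                    raise ValueError("overlap_bp set on the first planted unit")
                prev = unit_seqs[-1]
                if p.overlap_bp >= min(p.length, len(prev)):
                    raise ValueError("overlap_bp spans an entire copy")
                seq[: p.overlap_bp] = prev[-p.overlap_bp :]
            unit_seqs.append(seq)

        # lay out copies: free copies are placed with margins; an
        # overlap-linked copy is pinned to its predecessor's second copy
        free_lengths = []
        for i, p in enumerate(config.planted):
            free_lengths.append(p.length)  # copy a, always free
            if p.overlap_bp == 0:
                free_lengths.append(p.length)  # copy b, free
        placement = _place_copies(rng, L, free_lengths, margin)
        if placement is None:
            continue
        placement.sort(key=lambda t: t[2])
        slots = [(s, l) for s, l, _ in placement]

        expected: set[Match] = set()
        ok = True
        slot_i = 0
        copy_b_of: dict[int, tuple[int, int]] = {}
        for i, p in enumerate(config.planted):
            sa, la = slots[slot_i]
            slot_i += 1
            if p.overlap_bp == 0:
                sb, lb = slots[slot_i]
                slot_i += 1
            else:
                prev_b_start, prev_len = copy_b_of[i - 1]
                sb = (prev_b_start + prev_len - p.overlap_bp) % L
                lb = p.length
                if sb + lb > L:  # keep pinned copies unwrapped for simplicity
                    ok = False
                    break
            copy_b_of[i] = (sb, p.length)
            u = unit_seqs[i]
            bg[sa : sa + la] = u
            if p.orientation == "direct":
                bg[sb : sb + lb] = u
            else:
                bg[sb : sb + lb] = np.frombuffer(
                    revcomp(_to_str(u)).encode(), dtype=np.uint8
                )
            lo, hi = sorted((sa, sb))
            expected.add(Match(lo, hi, p.length, p.orientation))
        if not ok:
            continue

        genome = CircularGenome("synthetic", _to_str(bg))
        found = maximal_pair_matches(genome, config.min_repeat_len)
        if found != expected:
            continue
        units = find_repeats(genome, config.min_repeat_len)
        pairs = classify_pairs(units, L)
        return genome, pairs
    raise RuntimeError(
        "could not build a genome free of accidental repeats after 30 draws"
    )


def generate_decoy(
    length: int = 20_000, gc: float = 0.38,
    rng: np.random.Generator | None = None, seed: int = 1,
) -> CircularGenome:
    """A plastid-like contaminant circle (lower GC, no relation to the target)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return CircularGenome("decoy", _to_str(_random_bases(rng, length, gc)))


def _fragment(rng, mol: str, frag_len: int) -> str:
    L = len(mol)
    start = int(rng.integers(0, L))
    doubled = mol + mol
    return doubled[start : start + frag_len]


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return _to_str(arr)


def simulate_reads(
    genome: CircularGenome,
    pair: RepeatPair,
    f: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    decoy: CircularGenome | None = None,
) -> tuple[list[ReadPair], list[str]]:
    """Paired-end reads from a reference/recombined molecule mixture.

    Fragments of length N(insert_mean, insert_sd) are drawn uniformly per
    base from a population in which a fraction ``1-f`` of molecules is the
    reference circle and ``f`` its recombination products (chosen
    proportionally to their lengths, i.e. uniformly per base across the
    recombined state).  Returns the reads plus a truth label per pair:
    ``ref``, ``rec``, ``decoy`` or ``nuclear``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ok, reason = assessability(
        pair, config.read_length, config.insert_mean
    )
    if f > 0 and not ok:
        raise ValueError(f"cannot simulate recombined molecules: {reason}")
    products = recombine_genome(genome, pair).products if f > 0 else []
    plens = np.array([p.length for p in products], dtype=float)
    pweights = plens / plens.sum() if len(products) else None

    n_decoy = int(round(config.n_pairs * config.decoy_fraction))
    n_nuclear = int(round(config.n_pairs * config.nuclear_fraction))
    n_genomic = config.n_pairs - n_decoy - n_nuclear
    if n_decoy > 0 and decoy is None:
        decoy = generate_decoy(rng=rng)

    rl = config.read_length
    reads: list[ReadPair] = []
    labels: list[str] = []

    # homology stretch for nuclear-like chimeras: anchored on the repeat
    # locus so it reaches the conformation members, but shorter than the
    # aligned-length filter
    hom_len = 70
    hom_src_start = pair.copy_a.start - hom_len // 2

    def emit(name: str, frag: str, label: str) -> None:
        m1 = _apply_errors(rng, frag[:rl], config.error_rate)
        m2 = _apply_errors(rng, revcomp(frag[-rl:]), config.error_rate)
        reads.append(ReadPair(name, m1, m2))
        labels.append(label)

    for i in range(n_genomic):
        frag_len = max(rl, int(round(rng.normal(config.insert_mean,
                                                config.insert_sd))))
        if rng.random() < f:
            mol = products[int(rng.choice(len(products), p=pweights))]
            frag_len = min(frag_len, mol.length)
            emit(f"sim_{i}", _fragment(rng, mol.seq, frag_len), "rec")
        else:
            frag_len = min(frag_len, genome.length)
            emit(f"sim_{i}", _fragment(rng, genome.seq, frag_len), "ref")

    for i in range(n_decoy):
        frag_len = max(rl, int(round(rng.normal(config.insert_mean,
                                                config.insert_sd))))
        frag_len = min(frag_len, decoy.length)
        emit(f"decoy_{i}", _fragment(rng, decoy.seq, frag_len), "decoy")

    for i in range(n_nuclear):
        frag_len = max(rl, int(round(rng.normal(config.insert_mean,
                                                config.insert_sd))))
        hom = genome.window(hom_src_start, hom_len, "+")
        tail = _to_str(_random_bases(rng, frag_len - hom_len, 0.5))
        emit(f"nuc_{i}", hom + tail, "nuclear")

    return reads, labels
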