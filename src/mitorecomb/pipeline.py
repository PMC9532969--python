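"""End-to-end drivers tying the pipeline stages together.

Two entry points: :func:`estimate_pair_frequency` runs conformation building,
read assignment and frequency estimation for one repeat pair of a real or
synthetic genome; :func:`simulate_and_estimate` is the closed loop used for
calibration -- it plants a repeat pair, simulates reads at a known recombined
molecule fraction, and recovers that fraction with the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assign import AssignmentCounts, assign_read_pairs
from .conformations import assessability, build_conformations
from .repeats import RepeatPair
from .sequence_io import CircularGenome, ReadPair
from .stats import RecombinationResult, recombination_frequency
from .synthetic_data import (
    PlantedRepeat,
    SimulationConfig,
    generate_decoy,
    generate_genome,
    simulate_reads,
)


def all_pair_copies(pairs) -> list:
    """Deduplicated repeat copies across a set of pairs (for flank truncation)."""
    seen = {}
    for p in pairs:
        for c in (p.copy_a, p.copy_b):
            seen[(c.start, c.end, c.strand)] = c
    return list(seen.values())


def estimate_pair_frequency(
    genome: CircularGenome,
    pair: RepeatPair,
    reads,
    decoys=(),
    flank_len: int = 300,
    all_copies=None,
    read_length: int = 150,
    insert_size: int = 300,
    min_aln: int = 100,
    min_anchor: int = 25,
    max_mismatch_rate: float = 0.02,
) -> tuple[RecombinationResult, AssignmentCounts | None]:
    """Assign reads to one pair's conformations and estimate its frequency.

    Unassessable pairs (repeat longer than the insert can bridge) are
    returned immediately with an NA result and no assignment.
    """
    ok, reason = assessability(pair, read_length, insert_size, min_anchor)
    if not ok:
        result = RecombinationResult(
            pair.pair_id, pair.repeat_length, pair.orientation,
            0, 0, float("nan"), float("nan"), float("nan"),
            assessable=False, note=reason,
        )
        return result, None
    confs = build_conformations(genome, pair, flank_len, all_copies)
    counts = assign_read_pairs(
        reads, confs, decoys, min_aln, min_anchor, max_mismatch_rate
    )
    result = recombination_frequency(
        counts, pair.repeat_length, pair.orientation
    )
    return result, counts


@dataclass
class SimulationStudy:
    """Everything the closed-loop calibration produces."""

    config: SimulationConfig
    genome: CircularGenome
    pair: RepeatPair
    counts: AssignmentCounts
    result: RecombinationResult
    labels: list[str]

    @property
    def n_discriminative(self) -> int:
        return self.counts.n_ref + self.counts.n_rec

    @property
    def estimate(self) -> float:
        return self.result.frequency

    def standard_error(self, f: float | None = None) -> float:
        """Binomial SE of the estimate at true fraction ``f`` (default: f̂)."""
        n = self.n_discriminative
        if n == 0:
            return float("nan")
        p = self.estimate if f is None else f
        return float(np.sqrt(p * (1 - p) / n))


def simulate_and_estimate(
    *,
    genome_length: int = 10_000,
    repeat_length: int = 200,
    orientation: str = "direct",
    f: float = 0.5,
    n_pairs: int = 5_000,
    seed: int = 0,
    error_rate: float = 0.0,
    decoy_fraction: float = 0.0,
    nuclear_fraction: float = 0.0,
    flank_len: int = 300,
    **assign_kwargs,
) -> SimulationStudy:
    """Plant one repeat pair, simulate a read mixture, recover the fraction."""
    config = SimulationConfig(
        genome_length=genome_length,
        planted=(PlantedRepeat(repeat_length, orientation),),
        n_pairs=n_pairs,
        error_rate=error_rate,
        recombined_fraction=f,
        decoy_fraction=decoy_fraction,
        nuclear_fraction=nuclear_fraction,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    genome, pairs = generate_genome(config, rng)
    pair = pairs[0]
    decoy = generate_decoy(rng=rng) if decoy_fraction > 0 else None
    reads, labels = simulate_reads(genome, pair, f, config, rng, decoy)
    confs = build_conformations(genome, pair, flank_len,
                                all_pair_copies(pairs))
    counts = assign_read_pairs(
        reads, confs, [decoy] if decoy is not None else (), **assign_kwargs
    )
    result = recombination_frequency(counts, pair.repeat_length,
                                     pair.orientation)
    return SimulationStudy(config, genome, pair, counts, result, labels)
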