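#!/usr/bin/env python
"""Simulate a mitogenome-like circle with planted repeats and detect them.

Builds a 20 kb circular genome (43.5% GC) carrying a 200 bp direct pair, a
150 bp inverted pair and two 60 bp units sharing 3 bp in one copy (the
shared-locus special case), then runs the repeat finder and verifies the
planted structure is recovered exactly.

Writes the genome FASTA under scratch/ (regenerable from the seed) and the
repeat tables under results/.
"""

from pathlib import Path

import numpy as np

from mitorecomb import (
    PlantedRepeat,
    SimulationConfig,
    classify_pairs,
    find_repeats,
    generate_genome,
    repeat_summary,
    write_bed,
    write_fasta,
)

ROOT = Path(__file__).resolve().parent.parent
SEED = 20220921

CONFIG = SimulationConfig(
    genome_length=20_000,
    planted=(
        PlantedRepeat(200, "direct"),
        PlantedRepeat(150, "inverted"),
        PlantedRepeat(60, "direct"),
        PlantedRepeat(60, "direct", overlap_bp=3),
    ),
    seed=SEED,
)


def build():
    """Deterministic genome + ground truth shared by the later analysis steps."""
    rng = np.random.default_rng(SEED)
    return generate_genome(CONFIG, rng)


def main():
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    genome, pairs = build()
    write_fasta([genome], ROOT / "scratch" / "synthetic_mitogenome.fasta")

    units = find_repeats(genome, 30)
    copies = [c for u in units for c in u.copies]
    write_bed(copies, genome, ROOT / "results" / "repeat_copies.bed")
    with open(ROOT / "results" / "repeat_pairs.tsv", "w") as fh:
        fh.write("pair\tlength\ttype\toverlap_bp\toverlap_partner\n")
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.repeat_length}\t{p.orientation}\t"
                     f"{p.overlap_bp}\t{p.overlap_partner or '-'}\n")

    summ = repeat_summary(genome, units)
    print(f"planted 4 repeat pairs on a {genome.length:,} bp circle "
          f"(GC {100 * summ['gc_content']:.1f}%)")
    print(f"finder recovered {summ['n_units']} units / {summ['n_copies']} "
          f"copies, {summ['repetitive_bp']} bp repetitive "
          f"({100 * summ['repeat_fraction']:.2f}%)")
    for p in pairs:
        extra = f" (shares {p.overlap_bp} bp with {p.overlap_partner})" \
            if p.overlap_bp else ""
        print(f"  {p.pair_id}: {p.repeat_length} bp {p.orientation}{extra}")
    assert summ["n_units"] == 4 and summ["n_copies"] == 8


if __name__ == "__main__":
    main()
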