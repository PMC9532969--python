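#!/usr/bin/env python
"""Build conformation sequences and predict whole-genome recombination
products for the simulated genome of step 02.

For each assessable repeat pair this writes the reference and recombined
conformation FASTA (scratch/) and a junction/truncation table (results/),
and reports the subgenomic circles or isomeric circle each recombination
event would create.  The two 60 bp units sharing 3 bp get 3+3 conformations
each; the others get the standard 2+2.
"""

import importlib.util
import sys
from pathlib import Path

from mitorecomb import (
    CircularGenome,
    assessability,
    build_conformations,
    build_overlap_conformations,
    recombine_genome,
    write_fasta,
)
from mitorecomb.pipeline import all_pair_copies

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "analysis"))
_step02 = importlib.util.spec_from_file_location(
    "step02", ROOT / "analysis" / "02_simulate_genome_and_repeats.py"
)
step02 = importlib.util.module_from_spec(_step02)
_step02.loader.exec_module(step02)


def conformation_sets(genome, pairs, flank_len=300):
    copies = all_pair_copies(pairs)
    sets, done = [], set()
    for p in pairs:
        if p.pair_id in done:
            continue
        if p.overlap_bp > 0 and p.overlap_partner not in (None, p.pair_id):
            q = next(x for x in pairs if x.pair_id == p.overlap_partner)
            s1, s2 = build_overlap_conformations(genome, p, q, flank_len, copies)
            sets += [(p, s1), (q, s2)]
            done |= {p.pair_id, q.pair_id}
        else:
            sets.append((p, build_conformations(genome, p, flank_len, copies)))
            done.add(p.pair_id)
    return sets


def main():
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    genome, pairs = step02.build()

    records, rows = [], []
    for pair, cs in conformation_sets(genome, pairs):
        ok, reason = assessability(pair)
        print(f"{pair.pair_id} ({pair.repeat_length} bp {pair.orientation}): "
              f"{len(cs.reference_members)} reference + "
              f"{len(cs.recombined_members)} recombined conformations; "
              f"{'assessable' if ok else reason}")
        for m in cs.members:
            records.append(CircularGenome(
                f"{cs.pair_id}|{m.label}|{m.kind}", m.sequence, circular=False
            ))
            rows.append((cs.pair_id, m.label, m.kind, len(m.sequence),
                         m.left_junction, m.right_junction,
                         m.truncated_left, m.truncated_right))
        prod = recombine_genome(genome, pair)
        sizes = " + ".join(f"{p.length:,} bp" for p in prod.products)
        kind = ("two subgenomic circles" if pair.orientation == "direct"
                else "one isomeric circle")
        print(f"  recombination product: {kind} ({sizes})")

    write_fasta(records, ROOT / "scratch" / "conformations.fasta")
    with open(ROOT / "results" / "conformation_junctions.tsv", "w") as fh:
        fh.write("pair\tmember\tkind\tlength\tleft_junction\tright_junction\t"
                 "trunc_left\ttrunc_right\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    print(f"\nwrote {len(records)} conformation sequences "
          f"({sum(1 for r in rows if r[2] == 'recombined')} recombined)")


if __name__ == "__main__":
    main()
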