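# mitorecomb

Repeat-mediated recombination analysis for circular plant mitochondrial
genomes.

## The problem

Flowering-plant mitogenomes evolve slowly in sequence but rapidly in
structure: repeated sequences recombine, so the "circular chromosome" of an
assembly is really a population of interconverting conformations.  A repeat
pair in **direct** orientation splits the circle into two smaller subgenomic
circles; an **inverted** pair flips the segment between the copies, giving an
isomeric circle.  How active each repeat is — what fraction of molecules
carry the recombined arrangement — is measurable from ordinary paired-end
sequencing: reads spanning a repeat together with its flanking single-copy
sequence discriminate the *reference* arrangements (`aa`, `bb`) from the
*recombined* ones (`ab`, `ba`).

`mitorecomb` implements that measurement end to end for a circular
mitogenome:

1. **repeats** — find all maximal exact repeats ≥ 30 bp in both orientations,
   wrap-aware across the linearization origin, and classify copy pairs as
   direct or inverted;
2. **conformations** — build, per repeat pair, the reference and recombined
   local sequences (repeat ± 300 bp single-copy flanks), including the
   special case of two units sharing bases in one copy (3 reference + 3
   recombined conformations each), and predict the whole-genome products of
   each recombination event;
3. **assign** — place read pairs on the conformations with a deterministic
   gapless local aligner under decoy (plastid) filtering, a ≥ 100 bp
   aligned-length filter against nuclear homologs, and a junction-anchoring
   rule that keeps only conformation-discriminating pairs;
4. **stats** — estimate the recombination frequency

   ```
   f = (N_ab + N_ba) / (N_aa + N_bb + N_ab + N_ba)
   ```

   with a 95% Wilson score interval (f ≈ 50% means the conformations are at
   recombinational equilibrium, i.e. near-equimolar stoichiometry);
5. **synthetic_data** — a fully seeded generator of planted-repeat circular
   genomes and paired-end read mixtures at a known recombined molecule
   fraction, so every stage has closed-loop ground truth without downloads.

Repeats longer than the sequencing insert can bridge (e.g. a ~16 kb pair at
a 300 bp insert) are flagged *unassessable by short reads* rather than given
a spurious frequency.

## Worked example

Apply the estimator to published read-support counts for the repeat pairs of
the *Aeginetia indica* mitogenome (bundled in `mitorecomb.datasets`):

```python
from mitorecomb import AssignmentCounts, recombination_frequency

counts = AssignmentCounts.from_quad("R2", naa=235, nbb=206, nab=167, nba=163)
r = recombination_frequency(counts)
print(r.frequency_pct, r.ci_low, r.ci_high)
# 42.8 0.3937039... 0.4634887...
```

330 of 771 junction-spanning read pairs support the recombined arrangements:
this 237 bp direct repeat is recombining at 42.8% (95% CI 39.4–46.3%), close
to equilibrium.  `analysis/01_published_frequency_table.py` prints the full
table; the seven assessable pairs land between 42.8% and 51.4%, at most 7.2
points from the 50% equimolar expectation.

Closed loop on synthetic data (`analysis/02` → `analysis/04`): a 20 kb
circle (43.5% GC) with four planted repeat pairs, 12,000 read pairs
(150 bp, 300 ± 30 bp insert) with 5% plastid-like and 2% nuclear-like
contamination:

```
R1 (200 bp direct): true f=50.0%  estimated 50.8% [38.4, 63.2] from 59 junction-spanning pairs (|error| = 0.1 SE)
  filters: 603 decoy (600 true plastid-like), 1388 ambiguous, 0 short, 9950 unmapped
```

The planted stoichiometry is recovered within binomial uncertainty and all
600 plastid-like pairs end in the decoy tally, none in the support counters.

A thin CLI mirrors the library: `mitorecomb repeats|conformations|assign|simulate`.

## Layout

```
src/mitorecomb/    library: sequence_io, repeats, conformations, assign,
                   stats, synthetic_data, pipeline, datasets, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite with exhaustive brute-force oracles
docs/methods.md    model, conventions, numerical choices, limitations
```
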