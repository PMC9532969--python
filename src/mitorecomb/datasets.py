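"""Bundled published inputs.

Read-support counts reported for the eight large repeat pairs (R1-R8) of the
*Aeginetia indica* mitochondrial genome (GenBank TPA accession BK061406).
R1, a ~16 kb pair, is beyond what 150 bp / 300 bp-insert read pairs can
bridge and carries no counts.  R3 and R5 share 3 bp in one copy, so their
support is reported as summed reference/recombined totals over three
conformations each; the other pairs carry the four per-member counters.

These counts are *inputs* to the frequency estimator (see
``mitorecomb.stats``), not outputs of this package.
"""

from __future__ import annotations

from .assign import AssignmentCounts

# pair_id -> (repeat_length_bp, orientation, counts or None)
AEGINETIA_REPEAT_SUPPORT: list[dict] = [
    {"pair": "R1", "length": 16366, "type": "direct", "counts": None},
    {"pair": "R2", "length": 237, "type": "direct",
     "counts": {"Naa": 235, "Nbb": 206, "Nab": 167, "Nba": 163}},
    {"pair": "R3", "length": 233, "type": "inverted",
     "counts": {"Nref": 177, "Nrec": 150}},
    {"pair": "R4", "length": 186, "type": "inverted",
     "counts": {"Naa": 278, "Nbb": 250, "Nab": 272, "Nba": 286}},
    {"pair": "R5", "length": 181, "type": "direct",
     "counts": {"Nref": 449, "Nrec": 358}},
    {"pair": "R6", "length": 127, "type": "direct",
     "counts": {"Naa": 590, "Nbb": 600, "Nab": 662, "Nba": 584}},
    {"pair": "R7", "length": 111, "type": "direct",
     "counts": {"Naa": 548, "Nbb": 459, "Nab": 499, "Nba": 426}},
    {"pair": "R8", "length": 111, "type": "direct",
     "counts": {"Naa": 521, "Nbb": 447, "Nab": 473, "Nba": 442}},
]


def published_support_counts() -> list[dict]:
    """The bundled counts as rows of {pair, length, type, counts, assessable}.

    ``counts`` is an :class:`~mitorecomb.assign.AssignmentCounts` (or None
    for the short-read-unassessable R1).
    """
    rows = []
    for entry in AEGINETIA_REPEAT_SUPPORT:
        c = entry["counts"]
        if c is None:
            counts = None
        elif "Naa" in c:
            counts = AssignmentCounts.from_quad(
                entry["pair"], c["Naa"], c["Nbb"], c["Nab"], c["Nba"]
            )
        else:
            counts = AssignmentCounts.from_totals(
                entry["pair"], c["Nref"], c["Nrec"]
            )
        rows.append({
            "pair": entry["pair"],
            "length": entry["length"],
            "type": entry["type"],
            "counts": counts,
            "assessable": counts is not None,
        })
    return rows
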