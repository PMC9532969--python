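"""Recombination-frequency estimation and reporting.

The recombination frequency of a repeat pair is the fraction of
conformation-discriminating read pairs that support the recombined
arrangements:

    f = (Nab + Nba) / (Nab + Nba + Naa + Nbb)

i.e. recombined support over total informative support.  A value near 50%
indicates recombinational equilibrium -- the alternative conformations are
present in near-equimolar stoichiometry.  Because this is a binomial
proportion of counted read pairs, a 95% Wilson score interval is attached;
the report gives |f - 0.5| alongside the interval and leaves interpretation
of "equilibrium" to the reader.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .assign import AssignmentCounts

logger = logging.getLogger(__name__)

UNASSESSABLE_NOTE = "unassessable by short reads"


@dataclass
class RecombinationResult:
    pair_id: str
    repeat_length: int | None
    orientation: str | None
    n_ref: int
    n_rec: int
    frequency: float  # nan when no informative pairs
    ci_low: float
    ci_high: float
    assessable: bool = True
    note: str = ""
    counts: AssignmentCounts | None = None

    @property
    def frequency_pct(self) -> float:
        """Frequency in percent, rounded to one decimal."""
        return round(self.frequency * 100, 1)

    @property
    def distance_from_equilibrium(self) -> float:
        return abs(self.frequency - 0.5)


def recombination_frequency(
    counts: AssignmentCounts,
    repeat_length: int | None = None,
    orientation: str | None = None,
    assessable: bool = True,
    alpha: float = 0.05,
) -> RecombinationResult:
    """Frequency of recombined support with a Wilson score interval.

    All-zero counters yield an NA result (frequency ``nan``) with a warning
    rather than an exception.
    """
    n_ref, n_rec = counts.n_ref, counts.n_rec
    if n_ref < 0 or n_rec < 0:
        raise ValueError("negative support counters")
    total = n_ref + n_rec
    if total == 0:
        logger.warning("pair %s: no informative read pairs; frequency is NA",
                       counts.pair_id)
        return RecombinationResult(
            counts.pair_id, repeat_length, orientation, 0, 0,
            float("nan"), float("nan"), float("nan"),
            assessable=assessable, note="no informative pairs", counts=counts,
        )
    freq = n_rec / total
    lo, hi = proportion_confint(n_rec, total, alpha=alpha, method="wilson")
    return RecombinationResult(
        counts.pair_id, repeat_length, orientation, n_ref, n_rec,
        freq, float(lo), float(hi), assessable=assessable, counts=counts,
    )


_COLUMNS = [
    "pair", "repeat_length", "type", "Naa", "Nbb", "Nab", "Nba",
    "Nref", "Nrec", "frequency_pct", "ci_low_pct", "ci_high_pct", "status",
]


def report_table(results, path=None) -> pd.DataFrame:
    """Tabular report, one row per repeat pair.

    Pairs with the standard four members list Naa/Nbb/Nab/Nba; overlap pairs
    list summed Nref/Nrec only (per-member counts live on the attached
    ``AssignmentCounts``).  Unassessable pairs carry a status note and no
    frequency.  An empty input yields a header-only table.
    """
    rows = []
    for r in results:
        quad = {"Naa": None, "Nbb": None, "Nab": None, "Nba": None}
        if r.counts is not None and set(r.counts.member_counts) == {
            "aa", "bb", "ab", "ba"
        }:
            quad = {
                "Naa": r.counts.Naa, "Nbb": r.counts.Nbb,
                "Nab": r.counts.Nab, "Nba": r.counts.Nba,
            }
        if not r.assessable:
            rows.append({
                "pair": r.pair_id, "repeat_length": r.repeat_length,
                "type": r.orientation, **{k: None for k in quad},
                "Nref": None, "Nrec": None, "frequency_pct": None,
                "ci_low_pct": None, "ci_high_pct": None,
                "status": r.note or UNASSESSABLE_NOTE,
            })
            continue
        na = math.isnan(r.frequency)
        rows.append({
            "pair": r.pair_id, "repeat_length": r.repeat_length,
            "type": r.orientation, **quad,
            "Nref": r.n_ref, "Nrec": r.n_rec,
            "frequency_pct": None if na else r.frequency_pct,
            "ci_low_pct": None if na else round(r.ci_low * 100, 1),
            "ci_high_pct": None if na else round(r.ci_high * 100, 1),
            "status": r.note or "ok",
        })
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
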