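"""Standard-format I/O and the circular-coordinate sequence model.

Plant mitochondrial genomes typically map as circles, and every downstream
operation in this package -- repeat finding, conformation building, read
simulation, read assignment -- needs coordinate arithmetic that wraps through
the linearization origin.  :class:`CircularGenome` provides that contract:
coordinates are 0-based half-open on the forward strand of the deposited
sequence, and extraction with ``start > end`` wraps through the origin when
the molecule is circular.  The deposited origin is treated as arbitrary; all
operations built on top of this class are rotation-invariant.

``N`` characters are permitted (assemblies may carry them) but are defined to
match nothing, not even another ``N``; repeat seeding and read matching treat
them as mismatch-to-everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised when a sequence file violates the expected format."""


def revcomp(seq: str) -> str:
    """Reverse complement over the uppercase {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularGenome:
    """A single nucleotide sequence with wrap-aware coordinate access.

    Parameters
    ----------
    id : str
        Record label.
    seq : str
        Uppercase nucleotide string over {A,C,G,T,N}.
    circular : bool
        Whether coordinate extraction may wrap through the origin.  True for
        the mitogenome use case.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"genome {self.id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at a wrap-aware position (any integer)."""
        return self.seq[pos % len(self.seq)]

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Extract ``[start, end)`` on the given strand.

        The extracted length is always ``(end - start) mod length``; when
        ``start > end`` on a circular molecule the window wraps through the
        origin.  ``strand='-'`` returns the reverse complement of the forward
        extraction.
        """
        L = len(self.seq)
        if not (0 <= start < 2 * L and 0 <= end < 2 * L):
            raise ValueError(
                f"subseq coordinates out of range: start={start} end={end} L={L}"
            )
        if not self.circular and end < start:
            raise ValueError(
                f"non-circular sequence {self.id!r}: start {start} > end {end}"
            )
        n = (end - start) % L
        s = start % L
        out = (self.seq + self.seq)[s : s + n]
        return revcomp(out) if strand == "-" else out

    def window(self, start: int, length: int, strand: str = "+") -> str:
        """Extract ``length`` bases beginning at wrap-aware ``start``.

        Unlike :meth:`subseq` this is unambiguous for zero- and full-length
        windows, which internal code needs.
        """
        L = len(self.seq)
        if length < 0 or length > L:
            raise ValueError(f"window length {length} outside [0, {L}]")
        s = start % L
        out = (self.seq + self.seq)[s : s + length]
        return revcomp(out) if strand == "-" else out

    def rotated(self, k: int) -> "CircularGenome":
        """The same circle linearized at position ``k``."""
        k %= len(self.seq)
        return CircularGenome(self.id, self.seq[k:] + self.seq[:k], self.circular)

    def gc_content(self) -> float:
        """(G+C)/(A+C+G+T); N bases excluded from the denominator."""
        g = self.seq.count("G") + self.seq.count("C")
        denom = len(self.seq) - self.seq.count("N")
        return g / denom if denom else float("nan")


@dataclass
class ReadPair:
    """One paired-end read; mate2 is in sequencing orientation (the pipeline
    reverse-complements internally as needed)."""

    id: str
    mate1: str
    mate2: str
    qual1: str | None = None
    qual2: str | None = None

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise ValueError(f"read pair {self.id!r}: empty mate sequence")
        self.mate1 = self.mate1.upper()
        self.mate2 = self.mate2.upper()


def subseq(genome: CircularGenome, start: int, end: int, strand: str = "+") -> str:
    """Module-level convenience wrapper for :meth:`CircularGenome.subseq`."""
    return genome.subseq(start, end, strand)


def _validate_fasta_text(path: Path) -> None:
    """Light pre-scan so malformed input fails with a line number."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                in_record = True
                continue
            if not in_record:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            bad = set(stripped.upper()) - VALID_BASES
            if bad:
                raise FastaParseError(
                    f"{path}: line {lineno}: illegal characters {sorted(bad)}"
                )


def read_fasta(path: str | Path, circular: bool = True) -> list[CircularGenome]:
    """Read FASTA records as :class:`CircularGenome` objects.

    The circular flag comes from the caller, not from the file: FASTA has no
    topology field.  Sequences are uppercased.  An empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    _validate_fasta_text(path)
    records = [
        CircularGenome(rec.id, str(rec.seq), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _strip_mate_suffix(name: str) -> str:
    for suffix in ("/1", "/2"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read two FASTQ files in matched record order."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    pairs = []
    for rec1, rec2 in zip(it1, it2, strict=True):
        n1, n2 = _strip_mate_suffix(rec1.id), _strip_mate_suffix(rec2.id)
        if n1 != n2:
            raise FastaParseError(f"mate name mismatch: {rec1.id!r} vs {rec2.id!r}")
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        pairs.append(ReadPair(n1, str(rec1.seq), str(rec2.seq), q1, q2))
    return pairs


def write_fastq_pair(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.mate1)
            q2 = p.qual2 or "I" * len(p.mate2)
            f1.write(f"@{p.id}/1\n{p.mate1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.mate2}\n+\n{q2}\n")


def write_bed(copies: Sequence, genome: CircularGenome, path: str | Path) -> None:
    """BED6 export of repeat copies (0-based half-open, forward strand).

    A copy spanning the origin is written with ``end > genome length`` and a
    ``_wrap`` name suffix, since BED cannot represent wrapped intervals.
    """
    with open(path, "w") as fh:
        for c in copies:
            name = f"{c.unit_id}_{c.label}"
            if c.end > genome.length:
                name += "_wrap"
            fh.write(
                f"{genome.id}\t{c.start}\t{c.end}\t{name}\t{c.length}\t{c.strand}\n"
            )
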