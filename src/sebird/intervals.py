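"""Genomic intervals, BED I/O and FASTA genomes.

All coordinates in this package are 0-based half-open (BED convention):
an interval ``[start, end)`` covers ``end - start`` base pairs and two
intervals that merely touch (``a.end == b.start``) do not overlap.
Strand is ignored throughout; all sequences are plus-strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LABEL_TE = 0
LABEL_SE = 1

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomicInterval:
    """A labeled half-open genomic span.

    ``label`` is 0 for a typical enhancer (TE), 1 for a super-enhancer
    (SE), or ``None`` for unlabeled spans such as negative controls.
    """

    chrom: str
    start: int
    end: int
    label: int | None = None
    cell_line: str | None = None
    name: str | None = None
    score: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.score is not None and not (-1000 <= self.score <= 1000):
            raise ValueError(f"BED score {self.score} outside [-1000, 1000]")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, start: int, end: int) -> "GenomicInterval":
        return replace(self, start=start, end=end)


class Genome:
    """An in-memory genome: chromosome name -> uppercase sequence over ACGTN."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            seq = str(seq).upper()
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self._chroms[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> str:
        return self._chroms[chrom]

    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = SeqIO.parse(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._chroms.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def extract_sequence(genome: Genome, iv: GenomicInterval) -> str:
    """Plus-strand sequence of ``iv``; length always equals ``iv.length()``."""
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    chrom_len = genome.chrom_length(iv.chrom)
    if iv.end > chrom_len:
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {chrom_len}"
        )
    return genome[iv.chrom][iv.start : iv.end]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a 3-6 column tab-separated BED file (0-based half-open).

    Column 4 (name) is kept verbatim; a name equal to "SE"/"TE" or an
    integer 0/1 also sets the class label. Column 5 is the score,
    column 6 (strand) is ignored. Blank lines and track/browser/comment
    lines are skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates start={start} end={end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            label = _label_from_name(name)
            score: int | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = int(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer score") from exc
            cell_line = fields[6] if len(fields) > 6 and fields[6] != "." else None
            intervals.append(
                GenomicInterval(
                    chrom, start, end, label=label, cell_line=cell_line,
                    name=name, score=score,
                )
            )
    return intervals


def _label_from_name(name: str | None) -> int | None:
    if name is None:
        return None
    key = name.split(":", 1)[0].upper()
    if key == "SE" or key == "1":
        return LABEL_SE
    if key == "TE" or key == "0":
        return LABEL_TE
    return None


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 lines (chrom, start, end, name, score, strand='.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                name = iv.name
            elif iv.label == LABEL_SE:
                name = "SE"
            elif iv.label == LABEL_TE:
                name = "TE"
            else:
                name = "."
            score = "." if iv.score is None else str(iv.score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")
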