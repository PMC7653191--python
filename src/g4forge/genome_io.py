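"""Reading and writing the standard formats the pipeline touches.

FASTA genomes are held fully in memory as plain uppercase strings over the
alphabet {A, C, G, T, N}; IUPAC ambiguity codes and any other characters are
folded to N on load. Intervals follow the BED convention throughout:
0-based, half-open, with strand "+" or "-".
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "reverse_complement",
    "extract_sequence",
    "open_text",
]

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic locus with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class Genome:
    """In-memory mapping from chromosome name to an ACGTN sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        cleaned: dict[str, str] = {}
        for name, seq in sequences.items():
            if len(seq) < 1:
                raise ValueError(f"chromosome {name!r} is empty")
            seq = seq.upper()
            if not _VALID_BASES.issuperset(seq):
                seq = _NON_ACGTN.sub("N", seq)
            cleaned[name] = seq
        self._seqs = cleaned

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())


def open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    """Open a text file, transparently gzipped when the name ends in .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Sequences are uppercased, characters outside {A,C,G,T,N} become N and
    multi-line records are concatenated. Duplicate record names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seqs: dict[str, str] = {}
    with open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seqs:
                raise ValueError(f"duplicate record {record.id!r} in {path}")
            seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(seqs)


def write_fasta(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    path: str | Path,
    width: int = 80,
) -> None:
    """Write (name, sequence) pairs as FASTA (gzipped if path ends in .gz)."""
    pairs = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in pairs)
    with open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse BED3/BED6 into intervals.

    Coordinates are kept verbatim (0-based half-open); a missing strand
    column defaults to "+". ``track``/``browser`` and ``#`` comment lines
    are skipped. Malformed lines raise with the 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BED file not found: {path}")
    intervals: list[GenomicInterval] = []
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand == ".":
                strand = "+"
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open_text(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def _validate_seq(seq: str) -> None:
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"invalid characters in sequence: {bad}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N is its own complement."""
    _validate_seq(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(genome: Genome, interval: GenomicInterval) -> str:
    """Strand-aware slice of the genome at an interval.

    Minus-strand intervals return the reverse complement, so the result
    always reads 5'->3' on the strand the interval annotates.
    """
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval} exceeds chromosome length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
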