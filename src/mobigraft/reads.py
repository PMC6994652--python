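"""Read and alignment records, with FASTQ I/O."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

#: alignment record provenance tags
SOURCE_SAM = "sam"
SOURCE_TABULAR = "tabular-hit"
SOURCE_BUILTIN = "builtin"


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    mate_index: int = 1
    qualities: str | None = None  # phred+33 string

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One alignment (or recorded non-alignment) of a read against a genome.

    ``score`` is the aligner's comparable score: matches − mismatches for the
    builtin matcher, ``AS`` (or matches − NM) for SAM input, bitscore for
    tabular hits.  For records produced by the gapped builtin path, ``cigar``
    holds ``(op, length)`` pairs with ops in ``M/I/D`` (M = aligned column,
    I = insertion in the read, D = deletion from the read) and
    ``aligned_sequence``/``aligned_qualities`` are given on the genome's
    forward strand so pileups never need to re-orient reads.
    """

    read_id: str
    mate_index: int = 1
    mapped: bool = False
    target_genome: str | None = None
    contig: str | None = None
    position: int | None = None  # 1-based leftmost on the reference
    aligned_length: int = 0
    mismatches: int = 0
    score: float | None = None
    strand: str = "+"
    evalue: float | None = None
    source: str = SOURCE_BUILTIN
    cigar: list[tuple[str, int]] | None = None
    aligned_sequence: str | None = None
    aligned_qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.mapped:
            if self.contig is None or self.position is None:
                raise ValueError(
                    f"read {self.read_id!r}: mapped record without contig/position"
                )
            if self.score is None:
                raise ValueError(f"read {self.read_id!r}: mapped record without score")
        else:
            if self.contig is not None or self.position is not None:
                raise ValueError(
                    f"read {self.read_id!r}: unmapped record carries coordinates"
                )

    @property
    def reference_span(self) -> tuple[int, int]:
        """1-based inclusive reference interval covered by the alignment."""
        if not self.mapped:
            raise ValueError(f"read {self.read_id!r} is unmapped")
        if self.cigar:
            ref_len = sum(n for op, n in self.cigar if op in "MD")
        else:
            ref_len = self.aligned_length
        return self.position, self.position + ref_len - 1


# ---------------------------------------------------------------------- FASTQ
def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file into ReadRecords.

    Mate index is taken from an ``/1`` or ``/2`` read-id suffix when present
    (the suffix is stripped so mates share a fragment id).
    """
    out: list[ReadRecord] = []
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at {header!r}")
            rid = header[1:].split()[0]
            mate = 1
            if rid.endswith("/1") or rid.endswith("/2"):
                mate = int(rid[-1])
                rid = rid[:-2]
            out.append(ReadRecord(rid, seq.upper(), mate_index=mate, qualities=qual or None))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path,
                default_quality: int = 30) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            qual = r.qualities or chr(default_quality + 33) * len(r.sequence)
            suffix = f"/{r.mate_index}" if r.mate_index in (1, 2) else ""
            fh.write(f"@{r.read_id}{suffix}\n{r.sequence}\n+\n{qual}\n")
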