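"""Lightweight seed-and-extend read matcher.

This is the pipeline's built-in stand-in for an external short-read aligner
and cross-genome matcher: exact k-mer seeding into a genome index followed by
ungapped extension over the full read, on both strands.  It is deliberately
simple — no splicing, no quality-aware scoring — because read placement is
plumbing here, not the contribution; any SAM/tabular alignments from a real
aligner can be substituted at the module boundary.

A gapped mode (seed + banded edit-distance extension) exists for the
resequencing path, where small insertions/deletions between the sequenced
genotype and the published reference must survive alignment to be callable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from .genome import GenomeSequence, reverse_complement
from .reads import AlignmentRecord, ReadRecord, SOURCE_BUILTIN

logger = logging.getLogger(__name__)

DEFAULT_SEED_LEN = 31
DEFAULT_MAX_MISMATCH_FRAC = 0.05


@dataclass
class KmerIndex:
    """Exact k-mer lookup table over a genome, plus byte arrays for scoring."""

    genome: GenomeSequence
    k: int = DEFAULT_SEED_LEN
    _table: dict[str, list[tuple[str, int]]] = field(init=False, repr=False)
    _arrays: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        table: dict[str, list[tuple[str, int]]] = {}
        arrays: dict[str, np.ndarray] = {}
        for cid, seq in self.genome.contigs.items():
            arrays[cid] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for i in range(len(seq) - self.k + 1):
                table.setdefault(seq[i : i + self.k], []).append((cid, i))
        self._table = table
        self._arrays = arrays

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])

    def contig_array(self, contig: str) -> np.ndarray:
        return self._arrays[contig]


def _seed_offsets(read_len: int, k: int, n_seeds: int = 3) -> list[int]:
    if read_len < k:
        return []
    last = read_len - k
    offs = {0, last, last // 2} if n_seeds >= 3 else {0, last}
    return sorted(offs)


def _candidate_starts(seq: str, index: KmerIndex) -> set[tuple[str, int]]:
    """Diagonal starts (contig, 0-based) implied by exact seed hits."""
    candidates: set[tuple[str, int]] = set()
    for off in _seed_offsets(len(seq), index.k):
        for contig, pos in index.lookup(seq[off : off + index.k]):
            candidates.add((contig, pos - off))
    return candidates


def _ungapped_best(seq: str, index: KmerIndex) -> tuple[int, str, int] | None:
    """Best full-length ungapped placement: (mismatches, contig, 0-based start)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    length = len(seq)
    best: tuple[int, str, int] | None = None
    for contig, start in sorted(_candidate_starts(seq, index)):
        garr = index.contig_array(contig)
        if start < 0 or start + length > len(garr):
            continue
        mm = int(np.count_nonzero(garr[start : start + length] != arr))
        if best is None or (mm, contig, start) < best:
            best = (mm, contig, start)
    return best


def builtin_align(
    reads: list[ReadRecord],
    genome: GenomeSequence,
    seed_len: int = DEFAULT_SEED_LEN,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    index: KmerIndex | None = None,
) -> list[AlignmentRecord]:
    """Ungapped seed-and-extend alignment of reads against a genome.

    Each read is seeded at up to three offsets on both strands; every seeded
    diagonal is scored by full-length Hamming comparison.  The read is
    reported mapped at its best locus iff the mismatch fraction is at most
    ``max_mismatch_frac``; ties break deterministically by (contig, position),
    forward strand first.  ``score`` is matches − mismatches.
    """
    if index is None:
        index = KmerIndex(genome, k=seed_len)
    elif index.k != seed_len:
        raise ValueError(f"index k={index.k} does not match seed_len={seed_len}")
    out: list[AlignmentRecord] = []
    for read in reads:
        placement = None  # (mismatches, contig, start, strand)
        for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
            best = _ungapped_best(seq, index)
            if best is not None:
                cand = (best[0], best[1], best[2], strand)
                if placement is None or cand < placement:
                    placement = cand
        length = len(read)
        if placement is not None and placement[0] <= max_mismatch_frac * length:
            mm, contig, start, strand = placement
            out.append(
                AlignmentRecord(
                    read_id=read.read_id, mate_index=read.mate_index, mapped=True,
                    target_genome=genome.name, contig=contig, position=start + 1,
                    aligned_length=length, mismatches=mm,
                    score=float(length - 2 * mm), strand=strand, source=SOURCE_BUILTIN,
                )
            )
        else:
            out.append(
                AlignmentRecord(
                    read_id=read.read_id, mate_index=read.mate_index, mapped=False,
                    target_genome=genome.name, source=SOURCE_BUILTIN,
                )
            )
    return out


# ------------------------------------------------------------- gapped mode
_PAD = 16  # window slack around a seeded diagonal; > max callable indel length


def _affine_aligner():
    """Affine-gap infix aligner: one long gap beats several short ones.

    Edit-distance alignment (unit costs) is ambiguous about gap placement and
    happily splits a contiguous indel into equal-cost fragments; an affine
    gap-open penalty makes the contiguous representation the unique optimum,
    which is what a variant caller needs to see.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    aligner.end_deletion_score = 0.0  # window overhang at either end is free
    return aligner


def _affine_cigar(aligner, window: str, seq: str) -> tuple[int, list[tuple[str, int]]]:
    """Realign a read inside its window; return (0-based start, M/I/D cigar)."""
    aln = aligner.align(window, seq)[0]
    target_blocks, query_blocks = aln.aligned
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    start = int(target_blocks[0][0])
    prev_t = start
    prev_q = int(query_blocks[0][0])
    push("I", prev_q)  # leading unaligned read bases (rare; keep read fully spent)
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        push("D", int(t0) - prev_t)
        push("I", int(q0) - prev_q)
        push("M", int(t1) - int(t0))
        prev_t, prev_q = int(t1), int(q1)
    push("I", len(seq) - prev_q)  # trailing unaligned read bases
    # leading insertions carry no reference anchor; fold them into the first op
    while ops and ops[0][0] == "D":
        start += ops[0][1]
        ops.pop(0)
    return start, ops


def _parse_edlib_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            op = "M" if ch in "=XM" else ch
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))
    return ops


def align_reads_gapped(
    reads: list[ReadRecord],
    genome: GenomeSequence,
    seed_len: int = DEFAULT_SEED_LEN,
    max_edit_frac: float = 0.15,
    index: KmerIndex | None = None,
    default_quality: int = 30,
) -> list[AlignmentRecord]:
    """Seeded gapped alignment (edit distance) for the resequencing path.

    Candidate windows come from exact k-mer seeds as in :func:`builtin_align`;
    each window is aligned with an infix edit-distance alignment so small
    indels between genotype and reference are represented explicitly in the
    CIGAR.  ``aligned_sequence``/``aligned_qualities`` are reported on the
    genome's forward strand, ready for pileup.
    """
    if index is None:
        index = KmerIndex(genome, k=seed_len)
    out: list[AlignmentRecord] = []
    for read in reads:
        length = len(read)
        best = None  # (edit, contig, pos0, strand, cigar_ops, seq, quals)
        for strand in ("+", "-"):
            seq = read.sequence if strand == "+" else reverse_complement(read.sequence)
            quals = None
            if read.qualities is not None:
                q = [ord(c) - 33 for c in read.qualities]
                quals = q if strand == "+" else q[::-1]
            seen_windows: set[tuple[str, int]] = set()
            for contig, start in sorted(_candidate_starts(seq, index)):
                contig_seq = genome.contigs[contig]
                wstart = max(0, start - _PAD)
                wkey = (contig, wstart // _PAD)
                if wkey in seen_windows:
                    continue
                seen_windows.add(wkey)
                wend = min(len(contig_seq), start + length + _PAD)
                window = contig_seq[wstart:wend]
                if len(window) < length // 2:
                    continue
                res = edlib.align(seq, window, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                # fast path: a perfect hit needs no cigar surgery
                pos0 = wstart + res["locations"][0][0]
                cand = (res["editDistance"], contig, pos0, strand,
                        _parse_edlib_cigar(res["cigar"]), seq, quals)
                if best is None or cand[:4] < best[:4]:
                    best = cand
        if best is not None and best[0] <= max_edit_frac * length:
            edit, contig, pos0, strand, cigar, seq, quals = best
            if any(op in "ID" for op, _ in cigar):
                # realign with affine gaps so indels stay contiguous
                if not hasattr(align_reads_gapped, "_aligner"):
                    align_reads_gapped._aligner = _affine_aligner()
                contig_seq = genome.contigs[contig]
                wstart = max(0, pos0 - _PAD)
                wend = min(len(contig_seq), pos0 + length + _PAD)
                offset, cigar = _affine_cigar(
                    align_reads_gapped._aligner, contig_seq[wstart:wend], seq)
                pos0 = wstart + offset
            mm = edit - sum(n for op, n in cigar if op in "ID")
            out.append(
                AlignmentRecord(
                    read_id=read.read_id, mate_index=read.mate_index, mapped=True,
                    target_genome=genome.name, contig=contig, position=pos0 + 1,
                    aligned_length=length, mismatches=max(mm, 0),
                    score=float(length - 2 * edit), strand=strand,
                    source=SOURCE_BUILTIN, cigar=cigar, aligned_sequence=seq,
                    aligned_qualities=quals if quals is not None
                    else [default_quality] * length,
                )
            )
        else:
            out.append(
                AlignmentRecord(
                    read_id=read.read_id, mate_index=read.mate_index, mapped=False,
                    target_genome=genome.name, source=SOURCE_BUILTIN,
                )
            )
    return out
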