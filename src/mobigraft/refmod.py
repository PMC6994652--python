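"""Genotype-matched reference correction.

The genotype used in a grafting experiment is rarely the genotype the
published reference genome was assembled from.  Reads that differ from the
reference only through this genotype gap would otherwise be mistaken for
transcripts from the graft partner, so the pipeline first *personalises* each
reference: resequencing reads are aligned, variants are called from the
pileup, filtered for depth/homozygosity/quality, and incorporated into the
FASTA (producing ``Ref1-M``/``Ref2-M``); reads the reference cannot place at
all are assembled into extra scaffolds and appended.

Variant filters (defaults): depth >= 6 supporting reads, homozygous
(alt fraction >= 0.9), phred-like quality strictly > 20.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    GenomeSequence,
    CoordinateMap,
    GenomeError,
    ROLE_MODIFIED,
    ROLE_SCAFFOLD,
    reverse_complement,
)
from .reads import AlignmentRecord, ReadRecord
from .variants import SequenceVariant, left_align

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 6
DEFAULT_MIN_ZYGOSITY = 0.9
DEFAULT_MIN_QUALITY = 20.0
DEFAULT_BASE_QUALITY = 30  # assumed when alignments carry no qualities

# flank (aligned bases on each side) required before a read is counted as
# informative for an indel junction; guards against ambiguous read-end tails
_INDEL_FLANK = 4


def call_pileup_variants(
    alignments: list[AlignmentRecord],
    reference: GenomeSequence,
    default_quality: int = DEFAULT_BASE_QUALITY,
) -> list[SequenceVariant]:
    """Call candidate SNPs and short indels from a read pileup.

    Consumes mapped, CIGAR-bearing alignments (from
    :func:`mobigraft.align.align_reads_gapped` or SAM input) and emits one
    candidate per (contig, position, alt allele) with depth, alt support and
    mean alt base quality populated.  Columns where every read matches the
    reference emit nothing.  Indels are left-aligned before support counting
    so reads agree on one representation.
    """
    # per contig: coverage diff array + per-read spans for indel depth
    cov_diff: dict[str, np.ndarray] = {}
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    snp_obs: dict[tuple[str, int, str], list[float]] = defaultdict(list)
    ins_obs: dict[tuple[str, int, str], list[float]] = defaultdict(list)
    del_obs: dict[tuple[str, int, str], list[float]] = defaultdict(list)

    for contig, seq in reference.contigs.items():
        cov_diff[contig] = np.zeros(len(seq) + 2, dtype=np.int32)

    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.contig not in reference.contigs:
            raise GenomeError(
                f"alignment of read {aln.read_id!r} refers to unknown contig "
                f"{aln.contig!r}"
            )
        seq = aln.aligned_sequence
        if seq is None:
            raise ValueError(
                f"read {aln.read_id!r}: pileup requires alignments carrying the "
                "aligned sequence (gapped builtin or SAM input)"
            )
        cigar = aln.cigar or [("M", len(seq))]
        quals = aln.aligned_qualities or [default_quality] * len(seq)
        contig_seq = reference.contigs[aln.contig]
        ref_pos = aln.position  # 1-based
        read_pos = 0  # 0-based into seq
        start = ref_pos
        for op, n in cigar:
            if op == "M":
                if ref_pos - 1 + n > len(contig_seq):
                    raise GenomeError(
                        f"read {aln.read_id!r}: alignment runs past end of contig "
                        f"{aln.contig!r} ({ref_pos - 1 + n} > {len(contig_seq)})"
                    )
                for i in range(n):
                    base = seq[read_pos + i]
                    if base != contig_seq[ref_pos - 1 + i] and base != "N":
                        snp_obs[(aln.contig, ref_pos + i, base)].append(
                            float(quals[read_pos + i])
                        )
                ref_pos += n
                read_pos += n
            elif op == "I":
                inserted = seq[read_pos : read_pos + n]
                anchor = ref_pos - 1  # base preceding the insertion
                if (anchor >= 1
                        and read_pos >= _INDEL_FLANK
                        and len(seq) - (read_pos + n) >= _INDEL_FLANK):
                    pos, ref, alt = left_align(
                        contig_seq, anchor, contig_seq[anchor - 1],
                        contig_seq[anchor - 1] + inserted,
                    )
                    q = float(np.mean(quals[read_pos : read_pos + n]))
                    ins_obs[(aln.contig, pos, alt[1:])].append(q)
                read_pos += n
            elif op == "D":
                anchor = ref_pos - 1
                deleted = contig_seq[ref_pos - 1 : ref_pos - 1 + n]
                if (anchor >= 1
                        and read_pos >= _INDEL_FLANK
                        and len(seq) - read_pos >= _INDEL_FLANK):
                    pos, ref, alt = left_align(
                        contig_seq, anchor, contig_seq[anchor - 1] + deleted,
                        contig_seq[anchor - 1],
                    )
                    q = float(np.mean(
                        quals[max(read_pos - 2, 0) : read_pos + 2] or [default_quality]
                    ))
                    del_obs[(aln.contig, pos, ref[1:])].append(q)
                ref_pos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
        end = ref_pos - 1
        if end > len(contig_seq):
            raise GenomeError(
                f"read {aln.read_id!r}: position {end} out of bounds on "
                f"contig {aln.contig!r}"
            )
        cov_diff[aln.contig][start] += 1
        cov_diff[aln.contig][end + 1] -= 1
        spans[aln.contig].append((start, end))

    coverage = {c: np.cumsum(d)[:-1] for c, d in cov_diff.items()}  # index = pos
    span_arrays = {
        c: (np.array([s for s, _ in v], dtype=np.int64),
            np.array([e for _, e in v], dtype=np.int64))
        for c, v in spans.items()
    }

    out: list[SequenceVariant] = []
    # SNPs
    for (contig, pos, alt), qlist in snp_obs.items():
        depth = int(coverage[contig][pos])
        support = len(qlist)
        out.append(
            SequenceVariant(
                contig=contig, position=pos,
                ref=reference.contigs[contig][pos - 1], alt=alt,
                depth=max(depth, support), alt_support=support,
                quality=float(np.mean(qlist)),
            )
        )
    # indels: depth = reads spanning the junction with enough flank to be
    # informative (an edit-distance aligner represents a short tail across an
    # indel as mismatches, so tail reads can neither support nor refute it)
    for obs, is_ins in ((ins_obs, True), (del_obs, False)):
        for (contig, pos, allele), qlist in obs.items():
            starts, ends = span_arrays.get(contig, (np.array([]), np.array([])))
            d = len(allele)
            left_edge = pos - _INDEL_FLANK
            right_edge = (pos if is_ins else pos + d) + d + _INDEL_FLANK
            depth = int(np.count_nonzero((starts <= left_edge) & (ends >= right_edge)))
            support = len(qlist)
            anchor_base = reference.contigs[contig][pos - 1]
            ref = anchor_base if is_ins else anchor_base + allele
            alt = anchor_base + allele if is_ins else anchor_base
            out.append(
                SequenceVariant(
                    contig=contig, position=pos, ref=ref, alt=alt,
                    depth=max(depth, support), alt_support=support,
                    quality=float(np.mean(qlist)),
                )
            )
    out.sort(key=lambda v: (v.contig, v.position, v.ref, v.alt))
    return out


def filter_variants(
    candidates: list[SequenceVariant],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_zygosity: float = DEFAULT_MIN_ZYGOSITY,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> list[SequenceVariant]:
    """Retain candidates with depth >= min_depth, alt fraction >= min_zygosity
    and quality strictly greater than min_quality.  Order is preserved."""
    return [
        v for v in candidates
        if v.depth >= min_depth
        and v.zygosity_fraction >= min_zygosity
        and v.quality > min_quality
    ]


@dataclass
class ApplyResult:
    """Outcome of incorporating variants into a reference."""

    genome: GenomeSequence
    coordinate_map: CoordinateMap
    applied: list[SequenceVariant] = field(default_factory=list)
    rejected: list[SequenceVariant] = field(default_factory=list)

    def __iter__(self):  # allow (genome, coord_map) unpacking
        return iter((self.genome, self.coordinate_map))


def apply_variants(
    reference: GenomeSequence, variants: list[SequenceVariant]
) -> ApplyResult:
    """Incorporate variants into a reference genome.

    Variants are applied per contig in coordinate order; when two variants
    overlap on the reference, the first (by coordinate) wins and the second is
    skipped with a warning and reported in ``rejected``.  A reference-allele
    mismatch is a hard error.  Returns the modified genome (the input is
    untouched), a monotone coordinate map and the applied/rejected lists.
    """
    by_contig: dict[str, list[SequenceVariant]] = defaultdict(list)
    for v in variants:
        if v.contig not in reference.contigs:
            raise GenomeError(f"variant on unknown contig {v.contig!r}")
        by_contig[v.contig].append(v)

    new_contigs: dict[str, str] = {}
    anchors: dict[str, list[tuple[int, int]]] = {}
    applied: list[SequenceVariant] = []
    rejected: list[SequenceVariant] = []

    for contig, seq in reference.contigs.items():
        todo = sorted(by_contig.get(contig, []),
                      key=lambda v: (v.position, v.ref, v.alt))
        parts: list[str] = []
        contig_anchors: list[tuple[int, int]] = [(1, 1)]
        cursor = 0  # 0-based position of next unconsumed reference base
        delta = 0
        last_end = 0  # last consumed 1-based reference position
        for v in todo:
            start, end = v.ref_span
            if end > len(seq):
                raise GenomeError(
                    f"variant at {contig}:{v.position} runs past contig end"
                )
            if start <= last_end:
                logger.warning(
                    "skipping variant %s:%d %s>%s overlapping a previously "
                    "applied variant", contig, v.position, v.ref, v.alt,
                )
                rejected.append(v)
                continue
            observed = seq[start - 1 : end]
            if observed != v.ref:
                raise GenomeError(
                    f"reference allele mismatch at {contig}:{v.position}: "
                    f"variant says {v.ref!r}, reference has {observed!r}"
                )
            parts.append(seq[cursor : start - 1])
            parts.append(v.alt)
            cursor = end
            last_end = end
            delta += v.length_change
            if end + 1 <= len(seq):
                contig_anchors.append((end + 1, end + 1 + delta))
            applied.append(v)
        parts.append(seq[cursor:])
        new_contigs[contig] = "".join(parts)
        anchors[contig] = contig_anchors

    genome = GenomeSequence(
        name=f"{reference.name}-M", contigs=new_contigs, role=ROLE_MODIFIED
    )
    cmap = CoordinateMap(anchors)
    cmap.validate()
    return ApplyResult(genome=genome, coordinate_map=cmap,
                       applied=applied, rejected=rejected)


# ------------------------------------------------------------------ assembly
@dataclass
class ScaffoldSet:
    """Extra scaffolds assembled from reads the reference could not place."""

    scaffolds: GenomeSequence
    provenance: str = ""
    excluded_ids: set[str] = field(default_factory=set)

    def retained(self) -> dict[str, str]:
        return {
            cid: seq for cid, seq in self.scaffolds.contigs.items()
            if cid not in self.excluded_ids
        }


def assemble_unmapped(
    reads: list[ReadRecord],
    k: int = 31,
    min_scaffold_len: int = 200,
    provenance: str = "",
) -> ScaffoldSet:
    """Assemble unmapped reads into unitigs (a minimal de Bruijn stand-in).

    Builds a k-mer de Bruijn graph over the reads and both their reverse
    complements, compacts non-branching paths into unitigs, collapses each
    unitig with its reverse complement, and discards unitigs shorter than
    ``min_scaffold_len``.  Deterministic given identical input order.  This is
    interface-level assembly — scaffold quality is not the pipeline's
    contribution; a real assembler's scaffolds can be supplied instead.
    """
    usable = [r for r in reads if len(r) > k]
    if reads and not usable:
        logger.warning("assemble_unmapped: k=%d exceeds every read length", k)
    successors: dict[str, set[str]] = defaultdict(set)
    predecessors: dict[str, set[str]] = defaultdict(set)
    nodes: set[str] = set()
    for r in usable:
        for seq in (r.sequence, reverse_complement(r.sequence)):
            if "N" in seq:
                seq = max(seq.split("N"), key=len)
                if len(seq) <= k:
                    continue
            prev = seq[:k]
            nodes.add(prev)
            for i in range(1, len(seq) - k + 1):
                cur = seq[i : i + k]
                nodes.add(cur)
                successors[prev].add(cur)
                predecessors[cur].add(prev)
                prev = cur

    def is_start(node: str) -> bool:
        preds = predecessors.get(node, set())
        if len(preds) != 1:
            return True
        (p,) = preds
        return len(successors.get(p, set())) != 1

    visited: set[str] = set()
    unitigs: set[str] = set()

    def walk(start: str) -> None:
        path = [start]
        visited.add(start)
        cur = start
        while True:
            succs = successors.get(cur, set())
            if len(succs) != 1:
                break
            (nxt,) = succs
            if len(predecessors.get(nxt, set())) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = path[0] + "".join(n[-1] for n in path[1:])
        unitigs.add(min(seq, reverse_complement(seq)))

    for node in sorted(nodes):
        if node not in visited and is_start(node):
            walk(node)
    for node in sorted(nodes):  # leftovers are isolated cycles
        if node not in visited:
            walk(node)

    kept = sorted((s for s in unitigs if len(s) >= min_scaffold_len),
                  key=lambda s: (-len(s), s))
    contigs = {f"scaffold_{i:05d}": s for i, s in enumerate(kept, 1)}
    genome = GenomeSequence(
        name=f"{provenance or 'unmapped'}-scaffolds",
        contigs=contigs, role=ROLE_SCAFFOLD,
    )
    return ScaffoldSet(scaffolds=genome, provenance=provenance)


def build_modified_reference(
    reference: GenomeSequence,
    variants: list[SequenceVariant],
    scaffolds: ScaffoldSet | None = None,
    exclusion_ids: set[str] | None = None,
) -> ApplyResult:
    """Full reference correction: apply variants, then append retained scaffolds.

    Scaffold contig ids are namespaced with a ``scaffold`` prefix (the
    assembler already emits ``scaffold_*`` ids) so downstream gene assignment
    can distinguish personalised reference contigs from genotype-specific
    extra sequence.  An id collision between scaffolds and contigs is a hard
    error.
    """
    result = apply_variants(reference, variants)
    if scaffolds is not None:
        excluded = set(exclusion_ids or set()) | scaffolds.excluded_ids
        for cid, seq in scaffolds.scaffolds.contigs.items():
            if cid in excluded:
                continue
            name = cid if cid.startswith("scaffold") else f"scaffold_{cid}"
            if name in result.genome.contigs:
                raise GenomeError(
                    f"scaffold id {name!r} collides with a reference contig"
                )
            result.genome.contigs[name] = seq
    return result
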