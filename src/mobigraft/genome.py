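"""Core genomic containers: genomes, coordinate lift-over maps and gene models.

A grafting experiment involves four genome objects per species pair: the two
published references (``Ref1``/``Ref2``) and their genotype-corrected versions
(``Ref1-M``/``Ref2-M``) obtained by incorporating resequencing variants and
appending genotype-specific scaffolds.  Everything downstream (read mapping,
cross-genome matching, gene assignment) is expressed in the coordinates of
these objects, so they are kept deliberately simple: named, ordered sets of
upper-case contig strings over ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: genome roles used throughout the pipeline
ROLE_REFERENCE = "reference"
ROLE_MODIFIED = "modified"
ROLE_SCAFFOLD = "scaffold-extra"
_ROLES = (ROLE_REFERENCE, ROLE_MODIFIED, ROLE_SCAFFOLD)


class GenomeError(ValueError):
    """Raised for malformed genomes or coordinate violations."""


@dataclass
class GenomeSequence:
    """A named, ordered collection of contigs.

    Parameters
    ----------
    name
        Genome identifier, e.g. ``"Ref1"`` or ``"Ref2-M"``.
    contigs
        Ordered mapping of contig id to base string (``A/C/G/T/N`` only).
    role
        One of ``"reference"``, ``"modified"`` or ``"scaffold-extra"``.
    """

    name: str
    contigs: dict[str, str]
    role: str = ROLE_REFERENCE

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise GenomeError(f"unknown genome role {self.role!r}")
        for cid, seq in self.contigs.items():
            if not seq:
                raise GenomeError(f"contig {cid!r} in genome {self.name!r} is empty")
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise GenomeError(
                    f"contig {cid!r} in genome {self.name!r} contains "
                    f"non-ACGTN characters: {bad}"
                )

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return bases of ``contig`` in the 1-based inclusive window [start, end]."""
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise GenomeError(
                f"window {start}-{end} out of bounds for contig {contig!r} "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]

    def copy(self, name: str | None = None, role: str | None = None) -> "GenomeSequence":
        return GenomeSequence(
            name=name if name is not None else self.name,
            contigs=dict(self.contigs),
            role=role if role is not None else self.role,
        )

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None,
                   role: str = ROLE_REFERENCE) -> "GenomeSequence":
        path = Path(path)
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise GenomeError(f"duplicate contig id {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq).upper()
        if not contigs:
            raise GenomeError(f"no sequences found in {path}")
        return cls(name=name or path.stem, contigs=contigs, role=role)

    def to_fasta(self, path: str | Path) -> None:
        """Write the genome as FASTA, 60 columns per line, contig order preserved."""
        records = [
            SeqRecord(Seq(seq), id=cid, description="")
            for cid, seq in self.contigs.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CoordinateMap:
    """Monotone lift-over between an original genome and its modified version.

    Stores, per contig, anchor pairs ``(original_position, modified_position)``
    (1-based) such that between consecutive anchors the offset is constant.
    Built by :func:`mobigraft.refmod.apply_variants`; supports forward
    (original → modified) and backward lifts.  Positions falling inside a
    deleted interval lift to the anchor base preceding the deletion, so the
    forward/backward round trip is exact only outside deleted intervals.
    """

    anchors: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def identity(cls, genome: GenomeSequence) -> "CoordinateMap":
        return cls({cid: [(1, 1)] for cid in genome.contigs})

    def _check(self, contig: str) -> list[tuple[int, int]]:
        try:
            return self.anchors[contig]
        except KeyError:
            raise GenomeError(f"contig {contig!r} not present in coordinate map")

    def forward(self, contig: str, pos: int) -> int:
        """Lift a 1-based original-genome position to the modified genome."""
        anch = self._check(contig)
        i = bisect.bisect_right(anch, (pos, float("inf"))) - 1
        orig, mod = anch[i]
        if pos < orig:  # before the first anchor
            raise GenomeError(f"position {pos} precedes first anchor on {contig!r}")
        if i + 1 < len(anch):
            next_orig, next_mod = anch[i + 1]
            # inside a deleted interval: the original bases between two anchors
            # that advance the original coordinate faster than the modified one
            span_orig = next_orig - orig
            span_mod = next_mod - mod
            if pos - orig >= span_mod and span_mod < span_orig:
                return mod + span_mod - 1  # last surviving base before the gap
        return mod + (pos - orig)

    def backward(self, contig: str, pos: int) -> int:
        """Lift a 1-based modified-genome position back to the original genome."""
        anch = self._check(contig)
        inv = [(m, o) for (o, m) in anch]
        i = bisect.bisect_right(inv, (pos, float("inf"))) - 1
        mod, orig = inv[i]
        if pos < mod:
            raise GenomeError(f"position {pos} precedes first anchor on {contig!r}")
        if i + 1 < len(inv):
            next_mod, next_orig = inv[i + 1]
            span_mod = next_mod - mod
            span_orig = next_orig - orig
            if pos - mod >= span_orig and span_orig < span_mod:
                return orig + span_orig - 1  # inside an inserted interval
        return orig + (pos - mod)

    def validate(self) -> None:
        for contig, anch in self.anchors.items():
            for (o1, m1), (o2, m2) in zip(anch, anch[1:]):
                if not (o1 < o2 and m1 < m2):
                    raise GenomeError(
                        f"coordinate map for {contig!r} not strictly increasing "
                        f"at {(o1, m1)} -> {(o2, m2)}"
                    )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\toriginal_pos\tmodified_pos\n")
            for contig, anch in self.anchors.items():
                for orig, mod in anch:
                    fh.write(f"{contig}\t{orig}\t{mod}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoordinateMap":
        anchors: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("contig"):
                raise GenomeError(f"unexpected coordinate-map header in {path}")
            for line in fh:
                contig, orig, mod = line.rstrip("\n").split("\t")
                anchors.setdefault(contig, []).append((int(orig), int(mod)))
        return cls(anchors)


@dataclass
class GeneModel:
    """A gene as a strand-annotated set of exon intervals on one contig.

    Exons are 1-based inclusive ``(start, end)`` intervals, non-overlapping
    and sorted; ``exonic_length`` is the summed exon length used as the
    transcript-length term of FPKM.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.exons:
            raise GenomeError(f"gene {self.gene_id!r} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise GenomeError(f"gene {self.gene_id!r}: bad exon ({start}, {end})")
            if start <= prev_end:
                raise GenomeError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        """Concatenated exon sequence in transcription order (strand-aware)."""
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq


# --------------------------------------------------------------------- GFF3
def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (feature types gene/exon) from a GFF3 file.

    Uses an in-memory gffutils database; gene ids come from the ``ID``
    attribute of gene features, exons are attached through ``Parent``
    (directly, or via an mRNA intermediate).  A gene without exon children is
    modelled as a single exon spanning the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(gene.start, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=_merge_duplicate_exons(exons),
            )
        )
    return genes


def _merge_duplicate_exons(exons: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse identical/overlapping exon records from multiple transcripts."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(exons):
        if merged and start <= merged[-1][1] + 0:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "mobigraft") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def genes_by_id(genes: Iterable[GeneModel]) -> Mapping[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in out:
            raise GenomeError(f"duplicate gene id {g.gene_id!r}")
        out[g.gene_id] = g
    return out
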