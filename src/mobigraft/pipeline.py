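"""End-to-end detection: map, partition, quantify, call, summarise.

This module wires the stage modules together the way the two-figure workflow
runs in practice: every library is aligned to its resident genotype-matched
genome; unmapped reads are cross-matched against both genomes with a more
permissive threshold (similarity search is more tolerant than end-to-end
mapping); foreign-matching fragments are assigned to donor gene models; and
the caller applies A − (B + C), the foreign-FPKM threshold and the
both-replicates rule per direction and condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import KmerIndex, builtin_align, DEFAULT_SEED_LEN
from .genome import GenomeSequence, GeneModel
from .mobilecall import (
    CandidateEvidence,
    DEFAULT_MIN_FPKM,
    DOWNWARD,
    GraftDesign,
    MobileCall,
    UPWARD,
    CallSummary,
    ExpressionRecord,
    call_mobile_replicate,
    compute_fpkm,
    expressed_gene_set,
    intersect_replicates,
    summarize_calls,
)
from .readclass import (
    FragmentCountTable,
    ReadPartition,
    assign_fragments_to_genes,
    best_hits,
    partition_reads,
)
from .reads import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class DetectParams:
    """Thresholds of the detection stage (defaults are the pipeline's)."""

    min_fpkm: float = DEFAULT_MIN_FPKM  # foreign-FPKM mobility criterion (strict >)
    expression_min_fpkm: float = DEFAULT_MIN_FPKM  # donor "expressed" threshold
    expression_mode: str = "any-replicate"
    b_subtraction: str = "stringent"  # any control fragment excludes the gene
    min_margin: float = 0.0  # foreign-vs-own best-score margin
    seed_len: int = DEFAULT_SEED_LEN
    resident_max_mismatch_frac: float = 0.05
    crossmatch_max_mismatch_frac: float = 0.30
    min_hit_length: int = 50
    max_evalue: float = 1e-5
    allow_single_replicate: bool = False


@dataclass
class LibraryClassification:
    library_id: str
    partition: ReadPartition
    resident_counts: FragmentCountTable
    foreign_counts: FragmentCountTable
    total_resident_fragments: int


@dataclass
class DetectResult:
    calls: dict[tuple[str, str], set[str]]
    records: list[MobileCall]
    libraries: dict[str, LibraryClassification]
    donor_expression: dict[tuple[str, str], list[ExpressionRecord]]
    summary: CallSummary
    params: DetectParams

    def mobile_genes(self, direction: str, condition: str) -> set[str]:
        return self.calls.get((direction, condition), set())


def classify_library(
    reads: list[ReadRecord],
    resident_genome: GenomeSequence,
    partner_genome: GenomeSequence,
    resident_genes: list[GeneModel],
    partner_genes: list[GeneModel],
    params: DetectParams,
    library_id: str,
    resident_index: KmerIndex | None = None,
    partner_index: KmerIndex | None = None,
) -> LibraryClassification:
    """Two-pass classification of one library.

    Pass 1 maps all reads to the resident genome (strict mismatch budget).
    Pass 2 matches only the unmapped remainder against both genomes with the
    permissive cross-match budget; the partition adjudicates best scores.
    Resident-mapped fragments are assigned to resident gene models (feeding
    expression sets), foreign-matching fragments to partner gene models
    (feeding candidate sets).
    """
    if resident_index is None:
        resident_index = KmerIndex(resident_genome, k=params.seed_len)
    if partner_index is None:
        partner_index = KmerIndex(partner_genome, k=params.seed_len)

    resident_alns = builtin_align(
        reads, resident_genome, seed_len=params.seed_len,
        max_mismatch_frac=params.resident_max_mismatch_frac,
        index=resident_index,
    )
    mapped_ids = {a.read_id for a in resident_alns if a.mapped}
    unmapped_reads = [r for r in reads if r.read_id not in mapped_ids]

    own_alns = builtin_align(
        unmapped_reads, resident_genome, seed_len=params.seed_len,
        max_mismatch_frac=params.crossmatch_max_mismatch_frac,
        index=resident_index,
    )
    foreign_alns = builtin_align(
        unmapped_reads, partner_genome, seed_len=params.seed_len,
        max_mismatch_frac=params.crossmatch_max_mismatch_frac,
        index=partner_index,
    )
    partition = partition_reads(
        library_id, resident_alns,
        best_hits(own_alns, min_length=params.min_hit_length,
                  max_evalue=params.max_evalue),
        best_hits(foreign_alns, min_length=params.min_hit_length,
                  max_evalue=params.max_evalue),
        min_margin=params.min_margin,
    )
    resident_counts = assign_fragments_to_genes(
        best_hits([a for a in resident_alns if a.mapped],
                  min_length=params.min_hit_length, max_evalue=params.max_evalue),
        resident_genes,
    )
    foreign_counts = assign_fragments_to_genes(partition.foreign_hits, partner_genes)
    return LibraryClassification(
        library_id=library_id, partition=partition,
        resident_counts=resident_counts, foreign_counts=foreign_counts,
        total_resident_fragments=len(partition.resident_mapped),
    )


def detect(
    scion_genome: GenomeSequence,
    rootstock_genome: GenomeSequence,
    scion_genes: list[GeneModel],
    rootstock_genes: list[GeneModel],
    design: GraftDesign,
    reads: dict[str, list[ReadRecord]],
    params: DetectParams | None = None,
    indexes: tuple[KmerIndex, KmerIndex] | None = None,
) -> DetectResult:
    """Run the full bidirectional mobile-transcript detection.

    ``reads`` maps library id to its read list; the design names the four
    roles per condition.  Upward calls are rootstock genes detected in the
    heterograft scion; downward calls are scion genes detected in the
    heterograft rootstock.
    """
    params = params or DetectParams()
    min_reps = 1 if params.allow_single_replicate else 2
    design.validate(min_replicates=min_reps)

    if indexes is not None:
        idx_scion, idx_root = indexes
    else:
        idx_scion = KmerIndex(scion_genome, k=params.seed_len)
        idx_root = KmerIndex(rootstock_genome, k=params.seed_len)
    genome_of = {"scion": scion_genome, "rootstock": rootstock_genome}
    index_of = {"scion": idx_scion, "rootstock": idx_root}
    genes_of = {"scion": scion_genes, "rootstock": rootstock_genes}
    other = {"scion": "rootstock", "rootstock": "scion"}

    classifications: dict[str, LibraryClassification] = {}
    for lib in design.libraries:
        part = lib.sampled_part
        cls = classify_library(
            reads[lib.library_id], genome_of[part], genome_of[other[part]],
            genes_of[part], genes_of[other[part]], params, lib.library_id,
            resident_index=index_of[part], partner_index=index_of[other[part]],
        )
        lib.total_resident_fragments = cls.total_resident_fragments
        classifications[lib.library_id] = cls
        logger.info("library %s: %s", lib.library_id,
                    cls.partition.class_counts())

    conditions = sorted({l.condition for l in design.libraries})
    calls: dict[tuple[str, str], set[str]] = {}
    records: list[MobileCall] = []
    donor_expression: dict[tuple[str, str], list[ExpressionRecord]] = {}

    #        direction: (recipient role, control role, donor tissue role, donor part)
    layout = {
        UPWARD: ("heterograft-scion", "homograft-scion",
                 "heterograft-rootstock", "rootstock"),
        DOWNWARD: ("heterograft-rootstock", "homograft-rootstock",
                   "heterograft-scion", "scion"),
    }
    for condition in conditions:
        for direction, (recipient_role, control_role,
                        donor_role, donor_part) in layout.items():
            donor_genes = genes_of[donor_part]
            donor_universe = {g.gene_id for g in donor_genes}

            # B: genes with homograft-control foreign evidence
            b_genes: set[str] = set()
            for ctl in design.libraries_for(condition, control_role):
                cls = classifications[ctl.library_id]
                if params.b_subtraction == "stringent":
                    b_genes |= set(cls.foreign_counts.counts)
                elif params.b_subtraction == "lenient":
                    expr = compute_fpkm(cls.foreign_counts.counts, donor_genes,
                                        cls.total_resident_fragments,
                                        library_id=ctl.library_id)
                    b_genes |= {r.gene_id for r in expr
                                if r.fpkm > params.min_fpkm}
                else:
                    raise ValueError(
                        f"unknown b_subtraction mode {params.b_subtraction!r}"
                    )

            # C: donor-tissue-unexpressed genes
            donor_expr: list[ExpressionRecord] = []
            for donor_lib in design.libraries_for(condition, donor_role):
                cls = classifications[donor_lib.library_id]
                donor_expr.extend(compute_fpkm(
                    cls.resident_counts.counts, donor_genes,
                    cls.total_resident_fragments, library_id=donor_lib.library_id,
                ))
            donor_expression[(direction, condition)] = donor_expr
            expressed = expressed_gene_set(
                donor_expr, min_fpkm=params.expression_min_fpkm,
                mode=params.expression_mode,
            )
            c_genes = donor_universe - expressed

            per_replicate: list[dict[str, float]] = []
            per_replicate_counts: list[dict[str, int]] = []
            recipients = design.libraries_for(condition, recipient_role)
            for rec_lib in recipients:
                cls = classifications[rec_lib.library_id]
                evidence = CandidateEvidence(
                    direction=direction, condition=condition,
                    replicate=rec_lib.replicate,
                    a_counts=dict(cls.foreign_counts.counts),
                    b_genes=b_genes, c_genes=c_genes,
                )
                per_replicate.append(call_mobile_replicate(
                    evidence, donor_genes, cls.total_resident_fragments,
                    min_fpkm=params.min_fpkm,
                ))
                per_replicate_counts.append(dict(cls.foreign_counts.counts))
            final = intersect_replicates(
                per_replicate, allow_single=params.allow_single_replicate)
            calls[(direction, condition)] = final

            candidates = set().union(*(set(c) for c in per_replicate_counts)) \
                if per_replicate_counts else set()
            fpkm_by_rep: list[dict[str, float]] = []
            for rec_lib, counts in zip(recipients, per_replicate_counts):
                cls = classifications[rec_lib.library_id]
                fpkm_by_rep.append({
                    r.gene_id: r.fpkm
                    for r in compute_fpkm(counts, donor_genes,
                                          cls.total_resident_fragments)
                })
            for gene in sorted(candidates):
                call = MobileCall(
                    gene_id=gene, direction=direction, condition=condition,
                    foreign_counts={
                        lib.replicate: counts.get(gene, 0)
                        for lib, counts in zip(recipients, per_replicate_counts)
                    },
                    foreign_fpkm={
                        lib.replicate: table.get(gene, 0.0)
                        for lib, table in zip(recipients, fpkm_by_rep)
                    },
                    passed_control_subtraction=gene not in b_genes,
                    passed_expression_filter=gene not in c_genes,
                    passed_fpkm_threshold=all(
                        table.get(gene, 0.0) > params.min_fpkm
                        for table in fpkm_by_rep
                    ),
                    passed_replicate_intersection=gene in final,
                )
                records.append(call)

    summary = summarize_calls(calls, conditions)
    return DetectResult(calls=calls, records=records,
                        libraries=classifications,
                        donor_expression=donor_expression,
                        summary=summary, params=params)
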