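"""Mobile-transcript calling: candidate sets minus false-positive controls.

The caller operationalises the set logic of the detection workflow.  Per
direction (upward = rootstock→scion, downward = scion→rootstock) and per
condition, three data sets are formed from foreign-matching fragments:

* **A** — heterograft recipient-tissue fragments matching the donor genome
  (candidate mobile evidence);
* **B** — homograft control fragments matching the donor genome: whatever the
  homograft "transmits" is a cross-mapping artefact, so genes with control
  evidence are subtracted;
* **C** — donor-genome genes not expressed in the donor tissue: a transcript
  cannot move from where it is not made, so calls on such genes are
  expression false positives and subtracted.

A gene is called mobile in a replicate when it survives A − (B + C) and its
foreign FPKM exceeds 0.05; only genes called in every biological replicate
are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome import GeneModel, genes_by_id

logger = logging.getLogger(__name__)

DEFAULT_MIN_FPKM = 0.05
UPWARD = "upward"
DOWNWARD = "downward"


@dataclass
class SampleLibrary:
    library_id: str
    graft_combination: str  # e.g. "scion/rootstock" or "scion/scion"
    sampled_part: str  # "scion" | "rootstock"
    condition: str
    replicate: int
    total_resident_fragments: int = 0

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"library {self.library_id!r}: replicate must be >= 1")
        if self.sampled_part not in ("scion", "rootstock"):
            raise ValueError(
                f"library {self.library_id!r}: sampled_part must be scion|rootstock"
            )


@dataclass
class GraftDesign:
    """The library layout of one grafting experiment.

    Mobile calling needs, per condition, four roles: heterograft scion and
    rootstock (the recipients), and the two homografts (the false-positive
    controls), each with at least two biological replicates for final calls.
    """

    scion_genotype: str
    rootstock_genotype: str
    libraries: list[SampleLibrary] = field(default_factory=list)

    def role_of(self, lib: SampleLibrary) -> str:
        scion_g, _, rootstock_g = lib.graft_combination.partition("/")
        kind = "heterograft" if scion_g != rootstock_g else "homograft"
        return f"{kind}-{lib.sampled_part}"

    def libraries_for(self, condition: str, role: str) -> list[SampleLibrary]:
        libs = [
            l for l in self.libraries
            if l.condition == condition and self.role_of(l) == role
        ]
        return sorted(libs, key=lambda l: l.replicate)

    def validate(self, min_replicates: int = 2) -> None:
        conditions = sorted({l.condition for l in self.libraries})
        if not conditions:
            raise ValueError("graft design has no libraries")
        for condition in conditions:
            for role in ("heterograft-scion", "heterograft-rootstock",
                         "homograft-scion", "homograft-rootstock"):
                libs = self.libraries_for(condition, role)
                if not libs:
                    raise ValueError(
                        f"condition {condition!r}: missing {role} library — the "
                        "homograft false-positive control and both recipients "
                        "are mandatory"
                    )
                if len(libs) < min_replicates:
                    raise ValueError(
                        f"condition {condition!r}, role {role}: "
                        f"{len(libs)} replicate(s), need >= {min_replicates}"
                    )


@dataclass
class ExpressionRecord:
    gene_id: str
    library_id: str
    fragment_count: int
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if (self.fpkm == 0) != (self.fragment_count == 0):
            raise ValueError(
                f"{self.gene_id}: FPKM {self.fpkm} inconsistent with count "
                f"{self.fragment_count}"
            )


@dataclass
class CandidateEvidence:
    """One replicate's inputs to the per-replicate caller."""

    direction: str
    condition: str
    replicate: int
    a_counts: dict[str, int]  # gene -> foreign fragment count in recipient tissue
    b_genes: set[str]  # genes with homograft-control foreign evidence
    c_genes: set[str]  # genes unexpressed in the donor tissue


@dataclass
class MobileCall:
    gene_id: str
    direction: str
    condition: str
    foreign_counts: dict[int, int] = field(default_factory=dict)  # replicate ->
    foreign_fpkm: dict[int, float] = field(default_factory=dict)
    passed_control_subtraction: bool = False
    passed_expression_filter: bool = False
    passed_fpkm_threshold: bool = False
    passed_replicate_intersection: bool = False

    @property
    def is_mobile(self) -> bool:
        return (self.passed_control_subtraction
                and self.passed_expression_filter
                and self.passed_fpkm_threshold
                and self.passed_replicate_intersection)


# ------------------------------------------------------------------- FPKM
def compute_fpkm(
    counts: Mapping[str, int],
    genes: Sequence[GeneModel],
    total_fragments: int,
    library_id: str = "",
) -> list[ExpressionRecord]:
    """Fragments per kilobase of exonic length per million mapped fragments.

    ``fpkm(g) = count(g) / (exonic_length(g)/1000) / (total_fragments/1e6)``.
    ``total_fragments`` is the library's resident-mapped fragment total — the
    per-library sequencing-depth normaliser.
    """
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive for FPKM computation")
    models = genes_by_id(genes)
    missing = [g for g in counts if g not in models]
    if missing:
        raise KeyError(
            f"no gene model for counted gene(s): {sorted(missing)[:5]}"
        )
    out = []
    for gene_id in sorted(counts):
        count = counts[gene_id]
        length_kb = models[gene_id].exonic_length / 1000.0
        fpkm = count / length_kb / (total_fragments / 1e6)
        out.append(ExpressionRecord(gene_id=gene_id, library_id=library_id,
                                    fragment_count=count, fpkm=fpkm))
    return out


def expressed_gene_set(
    expr: Iterable[ExpressionRecord],
    min_fpkm: float = DEFAULT_MIN_FPKM,
    mode: str = "any-replicate",
) -> set[str]:
    """Genes with FPKM strictly above ``min_fpkm`` in donor-tissue libraries.

    ``mode="any-replicate"`` (default) requires one passing replicate;
    ``"all-replicates"`` requires every library the gene was quantified in to
    pass.  The complement of this set over the donor gene universe is the
    expression false-positive set C (or C′).
    """
    if mode not in ("any-replicate", "all-replicates"):
        raise ValueError(f"unknown mode {mode!r}")
    expr = list(expr)
    if not expr:
        logger.warning("expressed_gene_set: empty expression table")
        return set()
    passing: dict[str, list[bool]] = {}
    for rec in expr:
        passing.setdefault(rec.gene_id, []).append(rec.fpkm > min_fpkm)
    if mode == "any-replicate":
        return {g for g, flags in passing.items() if any(flags)}
    return {g for g, flags in passing.items() if all(flags)}


def call_mobile_replicate(
    evidence: CandidateEvidence,
    donor_genes: Sequence[GeneModel],
    recipient_total_fragments: int,
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> dict[str, float]:
    """One replicate's mobile-gene calls with their foreign FPKM.

    Returns the genes with foreign evidence (A count > 0) that survive
    subtraction of the homograft control set B and the donor-unexpressed set
    C, and whose foreign FPKM — computed from the A counts against the
    recipient library's resident-mapped total — strictly exceeds
    ``min_fpkm``.
    """
    if recipient_total_fragments <= 0:
        raise ValueError("recipient_total_fragments must be positive")
    a_counts = {g: c for g, c in evidence.a_counts.items() if c > 0}
    fpkm = {rec.gene_id: rec.fpkm
            for rec in compute_fpkm(a_counts, donor_genes, recipient_total_fragments)}
    return {
        g: fpkm[g]
        for g in sorted(a_counts)
        if g not in evidence.b_genes
        and g not in evidence.c_genes
        and fpkm[g] > min_fpkm
    }


def intersect_replicates(
    per_replicate_calls: Sequence[set[str] | dict[str, float]],
    allow_single: bool = False,
) -> set[str]:
    """Genes called in every biological replicate.

    Final mobile calls require detection in all replicates; a single-replicate
    input is a hard error unless ``allow_single`` explicitly permits the
    passthrough (with a loud warning).
    """
    sets = [set(c) for c in per_replicate_calls]
    if not sets:
        raise ValueError("no replicate call sets given")
    if len(sets) == 1:
        if not allow_single:
            raise ValueError(
                "replicate intersection requires >= 2 replicates; pass "
                "allow_single=True to accept single-replicate calls"
            )
        logger.warning(
            "single replicate: mobile calls are NOT replicate-supported"
        )
        return sets[0]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


@dataclass
class CallSummary:
    per_direction_condition: dict[tuple[str, str], int]
    shared: dict[tuple[str, str, str], int]  # (direction, cond_a, cond_b) -> n
    exclusive: dict[tuple[str, str], int]  # vs the other condition(s)


def summarize_calls(
    call_sets: Mapping[tuple[str, str], set[str]],
    conditions: Sequence[str] | None = None,
) -> CallSummary:
    """Count calls per (direction, condition) and their cross-condition overlap.

    ``call_sets`` maps (direction, condition) to the final gene set.  For each
    direction and condition pair the shared and exclusive set sizes are
    reported; exclusive + shared equals the condition total.
    """
    if conditions is None:
        conditions = sorted({cond for _, cond in call_sets})
    totals = {key: len(genes) for key, genes in call_sets.items()}
    shared: dict[tuple[str, str, str], int] = {}
    exclusive: dict[tuple[str, str], int] = {}
    directions = sorted({d for d, _ in call_sets})
    for direction in directions:
        for i, cond_a in enumerate(conditions):
            others: set[str] = set()
            for cond_b in conditions:
                if cond_b == cond_a:
                    continue
                others |= call_sets.get((direction, cond_b), set())
            genes_a = call_sets.get((direction, cond_a), set())
            exclusive[(direction, cond_a)] = len(genes_a - others)
            for cond_b in conditions[i + 1 :]:
                genes_b = call_sets.get((direction, cond_b), set())
                shared[(direction, cond_a, cond_b)] = len(genes_a & genes_b)
    return CallSummary(per_direction_condition=totals, shared=shared,
                       exclusive=exclusive)


def low_expression_fraction(
    mobile_genes: set[str],
    donor_expr: Iterable[ExpressionRecord],
    cutoff: float = 1.0,
) -> float | None:
    """Fraction of mobile genes whose donor-tissue mean FPKM is below ``cutoff``.

    Genes absent from the expression table count as FPKM 0.  Returns ``None``
    for an empty mobile set (the fraction is undefined, not zero).
    """
    if not mobile_genes:
        return None
    sums: dict[str, list[float]] = {}
    for rec in donor_expr:
        sums.setdefault(rec.gene_id, []).append(rec.fpkm)
    low = sum(
        1 for g in mobile_genes
        if (sum(sums.get(g, [0.0])) / len(sums.get(g, [0.0]))) < cutoff
    )
    return low / len(mobile_genes)


def expression_to_frame(expr: Iterable[ExpressionRecord]):
    import pandas as pd

    return pd.DataFrame(
        [(r.gene_id, r.library_id, r.fragment_count, r.fpkm) for r in expr],
        columns=["gene_id", "library_id", "fragment_count", "fpkm"],
    )


def calls_to_frame(calls: Iterable[MobileCall]):
    import pandas as pd

    rows = []
    for c in calls:
        reps = sorted(set(c.foreign_counts) | set(c.foreign_fpkm))
        rows.append({
            "gene_id": c.gene_id, "direction": c.direction,
            "condition": c.condition,
            **{f"count_rep{r}": c.foreign_counts.get(r, 0) for r in reps},
            **{f"fpkm_rep{r}": round(c.foreign_fpkm.get(r, 0.0), 6) for r in reps},
            "passed_control_subtraction": c.passed_control_subtraction,
            "passed_expression_filter": c.passed_expression_filter,
            "passed_fpkm_threshold": c.passed_fpkm_threshold,
            "passed_replicate_intersection": c.passed_replicate_intersection,
            "mobile": c.is_mobile,
        })
    return pd.DataFrame(rows)
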