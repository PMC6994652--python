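"""Synthetic grafting experiments with complete truth tables.

The simulator emulates the data-generating structure of a two-species
heterografting RNA-seq study so the whole detection pipeline can be exercised
and scored without any external data:

* two *published* reference genomes, the second derived from the first by an
  interspecies divergence process so homologous regions exist (the origin of
  cross-mapping false positives);
* an *experimental genotype* layer per species — SNPs, short indels and
  genotype-specific segments separating the grafted genotype from the
  published assembly (the gap reference correction repairs);
* per-tissue gene expression (log-normal, with an unexpressed fraction that
  feeds the expression false-positive sets);
* planted mobile genes per direction with recorded transmission fractions;
* uniformly sampled sequencing reads with per-base substitution error, every
  read carrying a provenance label in the truth set.

All randomness flows from one integer seed through a single numpy generator;
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import GenomeSequence, GeneModel, reverse_complement, write_gff3
from .mobilecall import GraftDesign, SampleLibrary, UPWARD, DOWNWARD
from .reads import ReadRecord, write_fastq
from .variants import SequenceVariant, left_align
from . import refmod

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment (defaults are the study conditions).

    Scale defaults (2 contigs x 200 kb per species, 200 genes, 50k single-end
    100 bp fragments per library, 2 replicates) target desk-scale full-pipeline
    runs; divergence and genotype-layer defaults emulate congeneric species
    grafted as non-reference genotypes.
    """

    seed: int
    # genome scale
    n_contigs: int = 2
    contig_length: int = 200_000
    n_genes: int = 200
    gene_length_min: int = 600
    gene_length_max: int = 1_800
    # interspecies divergence (species2 derived from species1)
    interspecies_snp_rate: float = 0.10
    interspecies_indel_rate: float = 0.005
    indel_max_len: int = 10
    # experimental-vs-reference genotype layer (per species)
    genotype_snps: int = 500
    genotype_insertions: int = 50
    genotype_deletions: int = 50
    genotype_segment_count: int = 2
    genotype_segment_length: int = 1_000
    min_variant_spacing: int = 100
    # expression
    expression_median: float = 5.0
    expression_sigma: float = 1.5
    unexpressed_fraction: float = 0.3
    # mobility
    mobile_per_direction: int = 20
    foreign_fpkm_range: tuple[float, float] = (200.0, 2_000.0)
    mobile_min_donor_expression: float = 1.0
    # sequencing
    read_length: int = 100
    fragments_per_library: int = 50_000
    error_rate: float = 0.01
    replicates: int = 2
    conditions: tuple[str, ...] = ("24C",)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation seed is mandatory")
        for name in ("interspecies_snp_rate", "interspecies_indel_rate",
                     "unexpressed_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_contigs", "contig_length", "n_genes", "read_length",
                     "fragments_per_library", "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gene_length_min < self.read_length:
            raise ValueError("genes must be at least one read long")

    def echo(self) -> dict:
        d = asdict(self)
        d["foreign_fpkm_range"] = list(self.foreign_fpkm_range)
        d["conditions"] = list(self.conditions)
        return d


@dataclass
class ReadProvenance:
    origin_species: str  # "species1" | "species2"
    gene_id: str
    mobile: bool


@dataclass
class TruthSet:
    """Everything the simulator planted, for parameter-recovery scoring."""

    genotype_variants: dict[str, list[SequenceVariant]] = field(default_factory=dict)
    genotype_segments: dict[str, dict[str, str]] = field(default_factory=dict)
    expression: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    # (direction, condition) -> gene -> transmission fraction
    mobile: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    provenance: dict[str, dict[str, ReadProvenance]] = field(default_factory=dict)

    def mobile_genes(self, direction: str, condition: str) -> set[str]:
        return set(self.mobile.get((direction, condition), {}))


@dataclass
class SpeciesData:
    name: str
    reference: GenomeSequence
    experimental: GenomeSequence
    genes: list[GeneModel]


@dataclass
class Experiment:
    """In-memory result of :func:`simulate_experiment`."""

    config: SimulationConfig
    species1: SpeciesData
    species2: SpeciesData
    design: GraftDesign
    reads: dict[str, list[ReadRecord]]
    truth: TruthSet
    mobile_targets: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict)


# ------------------------------------------------------------------ genomes
def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_base_except(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def _place_genes(
    genome: GenomeSequence, n_genes: int, lmin: int, lmax: int,
    rng: np.random.Generator, prefix: str,
) -> list[GeneModel]:
    """Place single-exon genes non-overlapping, proportional to contig length."""
    contigs = list(genome.contigs)
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    per_contig = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    i = 0
    while per_contig.sum() < n_genes:
        per_contig[i % len(contigs)] += 1
        i += 1
    genes: list[GeneModel] = []
    serial = 1
    for contig, k in zip(contigs, per_contig):
        clen = genome.length(contig)
        glens = rng.integers(lmin, lmax + 1, size=int(k))
        free = clen - int(glens.sum())
        if free < k + 1:
            raise ValueError(
                f"contig {contig!r} too short for {k} genes of {lmin}-{lmax} bp"
            )
        gaps = rng.multinomial(free - (int(k) + 1), [1.0 / (k + 1)] * (int(k) + 1))
        pos = 1
        for gi in range(int(k)):
            pos += int(gaps[gi]) + 1
            start = pos
            end = start + int(glens[gi]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(
                gene_id=f"{prefix}_g{serial:04d}", contig=contig,
                strand=strand, exons=[(start, end)],
            ))
            serial += 1
            pos = end + 1
    return genes


def _divergence_variants(
    genome: GenomeSequence, snp_rate: float, indel_rate: float,
    indel_max: int, rng: np.random.Generator,
) -> list[SequenceVariant]:
    """Draw per-base substitution/indel events along each contig.

    Events are drawn as a position walk: after each event the walk skips past
    the consumed bases, so variants never overlap and never run off the
    contig (the regenerate-locally contract).
    """
    out: list[SequenceVariant] = []
    for contig, seq in genome.contigs.items():
        pos = 2  # keep position 1 pristine as a global anchor
        limit = len(seq) - indel_max - 1
        while pos <= limit:
            r = rng.random()
            if r < snp_rate:
                ref = seq[pos - 1]
                out.append(SequenceVariant(
                    contig=contig, position=pos, ref=ref,
                    alt=_random_base_except(rng, ref),
                ))
                pos += 1
            elif r < snp_rate + indel_rate:
                d = int(rng.integers(1, indel_max + 1))
                anchor = seq[pos - 1]
                if rng.random() < 0.5:  # insertion
                    out.append(SequenceVariant(
                        contig=contig, position=pos, ref=anchor,
                        alt=anchor + _random_sequence(rng, d),
                    ))
                    pos += 2
                else:  # deletion
                    out.append(SequenceVariant(
                        contig=contig, position=pos,
                        ref=anchor + seq[pos : pos + d], alt=anchor,
                    ))
                    pos += d + 2
            else:
                pos += 1
    return out


def simulate_genome_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[tuple[GenomeSequence, list[GeneModel]],
           tuple[GenomeSequence, list[GeneModel]]]:
    """Simulate two homologous species references with gene models.

    Species 2 is derived from species 1 by the interspecies divergence
    process, so every species-1 gene has a lifted species-2 homolog — the
    structure that makes cross-genome read assignment genuinely hard.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contigs1 = {
        f"sp1_chr{i + 1}": _random_sequence(rng, config.contig_length)
        for i in range(config.n_contigs)
    }
    ref1 = GenomeSequence(name="Ref1", contigs=contigs1)
    genes1 = _place_genes(ref1, config.n_genes, config.gene_length_min,
                          config.gene_length_max, rng, "sp1")

    div = _divergence_variants(ref1, config.interspecies_snp_rate,
                               config.interspecies_indel_rate,
                               config.indel_max_len, rng)
    applied = refmod.apply_variants(ref1, div)
    contigs2 = {
        cid.replace("sp1_", "sp2_"): seq
        for cid, seq in applied.genome.contigs.items()
    }
    ref2 = GenomeSequence(name="Ref2", contigs=contigs2)
    cmap = applied.coordinate_map
    genes2: list[GeneModel] = []
    for g in genes1:
        start = cmap.forward(g.contig, g.start)
        end = cmap.forward(g.contig, g.end)
        genes2.append(GeneModel(
            gene_id=g.gene_id.replace("sp1_", "sp2_"),
            contig=g.contig.replace("sp1_", "sp2_"),
            strand=g.strand, exons=[(start, end)],
        ))
    return (ref1, genes1), (ref2, genes2)


def derive_experimental_genotype(
    reference: GenomeSequence,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenomeSequence, list[SequenceVariant], dict[str, str]]:
    """Mutate a published reference into the grafted genotype.

    Plants exactly the configured numbers of SNPs, insertions and deletions
    (spaced by at least ``min_variant_spacing`` so edits never interact) and
    appends ``genotype_segment_count`` genotype-specific segments as extra
    contigs.  Returns the experimental genome, the planted variants in the
    left-anchored convention reference correction consumes, and the segments.
    """
    n_total = config.genotype_snps + config.genotype_insertions + config.genotype_deletions
    spacing = max(config.min_variant_spacing, 2 * config.indel_max_len + 10)
    # allocate variants to contigs proportionally, then to distinct bins
    contigs = list(reference.contigs)
    lengths = np.array([reference.length(c) for c in contigs], dtype=float)
    per_contig = np.floor(n_total * lengths / lengths.sum()).astype(int)
    i = 0
    while per_contig.sum() < n_total:
        per_contig[i % len(contigs)] += 1
        i += 1

    kinds = (["SNP"] * config.genotype_snps
             + ["INS"] * config.genotype_insertions
             + ["DEL"] * config.genotype_deletions)
    kinds = list(rng.permutation(np.array(kinds, dtype=object)))

    variants: list[SequenceVariant] = []
    cursor = 0
    for contig, k in zip(contigs, per_contig):
        seq = reference.contigs[contig]
        margin = config.read_length + config.indel_max_len + 5
        n_bins = (len(seq) - 2 * margin) // spacing
        if n_bins < k:
            raise ValueError(
                f"contig {contig!r} too short for {k} variants at spacing {spacing}"
            )
        bins = np.sort(rng.choice(n_bins, size=int(k), replace=False))
        offsets = rng.integers(0, spacing // 2, size=int(k))
        for b, off in zip(bins, offsets):
            pos = margin + int(b) * spacing + int(off) + 1
            kind = kinds[cursor]
            cursor += 1
            ref_base = seq[pos - 1]
            if kind == "SNP":
                ref, alt = ref_base, _random_base_except(rng, ref_base)
            elif kind == "INS":
                d = int(rng.integers(1, config.indel_max_len + 1))
                ref, alt = ref_base, ref_base + _random_sequence(rng, d)
            else:
                d = int(rng.integers(1, config.indel_max_len + 1))
                ref, alt = ref_base + seq[pos : pos + d], ref_base
            # record truth in the left-anchored normal form the caller emits
            pos, ref, alt = left_align(seq, pos, ref, alt)
            variants.append(SequenceVariant(contig=contig, position=pos,
                                            ref=ref, alt=alt))

    applied = refmod.apply_variants(reference, variants)
    assert not applied.rejected, "planted variants must never overlap"
    experimental = applied.genome.copy(name=f"{reference.name}-exp",
                                       role="reference")
    segments: dict[str, str] = {}
    for s in range(config.genotype_segment_count):
        sid = f"{reference.name}_segment_{s + 1}"
        segments[sid] = _random_sequence(rng, config.genotype_segment_length)
        experimental.contigs[sid] = segments[sid]
    return experimental, variants, segments


# --------------------------------------------------------------- expression
def simulate_expression(
    genes: list[GeneModel],
    config: SimulationConfig,
    tissue: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Log-normal expression per gene with an unexpressed fraction set to 0.

    Values are on an FPKM-like relative scale (median ``expression_median``
    among expressed genes); read sampling weights are expression x exonic
    length, so these behave as expected FPKM up to depth normalisation.
    """
    levels = {}
    mu = math.log(config.expression_median)
    for g in genes:
        if rng.random() < config.unexpressed_fraction:
            levels[g.gene_id] = 0.0
        else:
            levels[g.gene_id] = float(rng.lognormal(mean=mu,
                                                    sigma=config.expression_sigma))
    return levels


def _choose_mobile(
    donor_genes: list[GeneModel],
    donor_expr: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Pick mobile genes and transmission fractions hitting a target
    foreign abundance.

    The transmission fraction is derived from a target foreign FPKM drawn
    log-uniformly from ``foreign_fpkm_range``:
    ``f = fpkm_target * W_resident / (1e9 * donor_expression)`` (capped at 1),
    where ``W_resident`` is the recipient library's total sampling weight.
    The cap plus the ``mobile_min_donor_expression`` eligibility floor keep
    fractions physical while leaving mobility uncorrelated with donor
    abundance above the floor.
    """
    eligible = sorted(
        g.gene_id for g in donor_genes
        if donor_expr.get(g.gene_id, 0.0) >= config.mobile_min_donor_expression
    )
    n = config.mobile_per_direction
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} donor genes eligible for mobility, need {n}"
        )
    chosen = sorted(rng.choice(np.array(eligible, dtype=object), size=n,
                               replace=False))
    lo, hi = config.foreign_fpkm_range
    targets = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    # W_resident is computed against the donor's own tissue weights at call
    # time in simulate_graft_reads; store the target and finalise f there.
    return {g: float(t) for g, t in zip(chosen, targets)}


# ------------------------------------------------------------------- reads
def _apply_errors(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        mask = rng.random(len(arr)) < rate
        n_err = int(mask.sum())
        if n_err:
            shifts = rng.integers(1, 4, size=n_err)
            idx = np.searchsorted(_BASES, arr[mask])  # A,C,G,T are sorted
            arr[mask] = _BASES[(idx + shifts) % 4]
        out.append(arr.tobytes().decode("ascii"))
    return out


def _sample_gene_reads(
    gene: GeneModel, genome: GenomeSequence, n: int,
    read_length: int, rng: np.random.Generator,
) -> list[str]:
    transcript = gene.spliced_sequence(genome)
    span = len(transcript) - read_length
    if span < 0:
        return []
    starts = rng.integers(0, span + 1, size=n)
    strands = rng.random(n) < 0.5
    out = []
    for start, rc in zip(starts, strands):
        seq = transcript[int(start) : int(start) + read_length]
        out.append(reverse_complement(seq) if rc else seq)
    return out


def simulate_graft_reads(
    design: GraftDesign,
    genomes: dict[str, GenomeSequence],
    genes: dict[str, list[GeneModel]],
    expression: dict[tuple[str, str], dict[str, float]],
    mobile_targets: dict[tuple[str, str], dict[str, float]],
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: TruthSet,
) -> dict[str, list[ReadRecord]]:
    """Sample every library's reads and record per-read provenance.

    Heterograft recipient libraries mix resident transcripts (sampled with
    weight expression x exonic length) with foreign transcripts of the
    planted mobile genes; homograft controls contain resident transcripts
    only.  ``mobile_targets`` holds target foreign FPKM per mobile gene; the
    realised transmission fraction is recorded in the truth set.
    """
    part_species = {"scion": "species1", "rootstock": "species2"}
    reads_by_lib: dict[str, list[ReadRecord]] = {}
    for lib in design.libraries:
        role = design.role_of(lib)
        resident_species = part_species[lib.sampled_part]
        donor_species = ("species2" if lib.sampled_part == "scion" else "species1")
        direction = UPWARD if lib.sampled_part == "scion" else DOWNWARD
        res_genes = genes[resident_species]
        res_genome = genomes[resident_species]
        res_expr = expression[(resident_species, lib.condition)]
        models = {g.gene_id: g for g in res_genes}
        entries: list[tuple[str, str, bool, float]] = []  # gene, species, mobile, w
        w_resident = 0.0
        for g in res_genes:
            w = res_expr.get(g.gene_id, 0.0) * g.exonic_length
            if w > 0:
                entries.append((g.gene_id, resident_species, False, w))
                w_resident += w
        if role.startswith("heterograft"):
            donor_expr = expression[(donor_species, lib.condition)]
            donor_models = {g.gene_id: g for g in genes[donor_species]}
            targets = mobile_targets.get((direction, lib.condition), {})
            mobile_truth = truth.mobile.setdefault((direction, lib.condition), {})
            for gene_id in sorted(targets):
                if gene_id not in donor_models:
                    raise ValueError(
                        f"mobile gene {gene_id!r} not in donor gene universe"
                    )
                e_d = donor_expr.get(gene_id, 0.0)
                if e_d <= 0:
                    raise ValueError(
                        f"mobile gene {gene_id!r} is unexpressed in donor tissue"
                    )
                f = targets[gene_id] * w_resident / (1e9 * e_d)
                if f > 1.0:
                    logger.debug("capping transmission fraction of %s at 1", gene_id)
                    f = 1.0
                mobile_truth[gene_id] = f
                w = e_d * f * donor_models[gene_id].exonic_length
                entries.append((gene_id, donor_species, True, w))
                models[gene_id] = donor_models[gene_id]

        weights = np.array([w for *_, w in entries])
        counts = rng.multinomial(config.fragments_per_library,
                                 weights / weights.sum())
        lib_reads: list[ReadRecord] = []
        lib_prov: dict[str, ReadProvenance] = {}
        serial = 0
        for (gene_id, species, is_mobile, _w), n in zip(entries, counts):
            if n == 0:
                continue
            genome = genomes[species]
            raw = _sample_gene_reads(models[gene_id], genome, int(n),
                                     config.read_length, rng)
            raw = _apply_errors(raw, config.error_rate, rng)
            for seq in raw:
                rid = f"{lib.library_id}:{serial:06d}"
                serial += 1
                lib_reads.append(ReadRecord(rid, seq))
                lib_prov[rid] = ReadProvenance(species, gene_id, is_mobile)
        reads_by_lib[lib.library_id] = lib_reads
        truth.provenance[lib.library_id] = lib_prov
    return reads_by_lib


def simulate_resequencing_reads(
    genome: GenomeSequence,
    coverage: float = 30.0,
    read_length: int = 100,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    id_prefix: str = "reseq",
) -> list[ReadRecord]:
    """Uniform whole-genome shotgun reads at the requested mean coverage."""
    if rng is None:
        rng = np.random.default_rng(seed)
    contigs = list(genome.contigs)
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    n_reads = int(math.ceil(lengths.sum() * coverage / read_length))
    picks = rng.choice(len(contigs), size=n_reads, p=lengths / lengths.sum())
    out: list[ReadRecord] = []
    for i, ci in enumerate(picks):
        contig = contigs[int(ci)]
        span = genome.length(contig) - read_length
        if span < 0:
            continue
        start = int(rng.integers(0, span + 1))
        seq = genome.contigs[contig][start : start + read_length]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        out.append(ReadRecord(f"{id_prefix}_{i:07d}", seq))
    if error_rate > 0:
        seqs = _apply_errors([r.sequence for r in out], error_rate, rng)
        out = [ReadRecord(r.read_id, s) for r, s in zip(out, seqs)]
    return out


# ------------------------------------------------------------- orchestration
def build_design(config: SimulationConfig,
                 scion_genotype: str = "scionG",
                 rootstock_genotype: str = "rootG") -> GraftDesign:
    libraries = []
    combos = {
        "heterograft-scion": (f"{scion_genotype}/{rootstock_genotype}", "scion"),
        "heterograft-rootstock": (f"{scion_genotype}/{rootstock_genotype}", "rootstock"),
        "homograft-scion": (f"{scion_genotype}/{scion_genotype}", "scion"),
        "homograft-rootstock": (f"{rootstock_genotype}/{rootstock_genotype}", "rootstock"),
    }
    for condition in config.conditions:
        for role, (combo, part) in combos.items():
            for rep in range(1, config.replicates + 1):
                libraries.append(SampleLibrary(
                    library_id=f"{condition}_{role}_rep{rep}",
                    graft_combination=combo, sampled_part=part,
                    condition=condition, replicate=rep,
                ))
    return GraftDesign(scion_genotype=scion_genotype,
                       rootstock_genotype=rootstock_genotype,
                       libraries=libraries)


def simulate_experiment(config: SimulationConfig) -> Experiment:
    """Run the full generator: genomes, genotypes, expression, mobility, reads."""
    rng = np.random.default_rng(config.seed)
    (ref1, genes1), (ref2, genes2) = simulate_genome_pair(config, rng)
    truth = TruthSet()
    exp1, var1, seg1 = derive_experimental_genotype(ref1, config, rng)
    exp2, var2, seg2 = derive_experimental_genotype(ref2, config, rng)
    truth.genotype_variants = {"species1": var1, "species2": var2}
    truth.genotype_segments = {"species1": seg1, "species2": seg2}

    expression: dict[tuple[str, str], dict[str, float]] = {}
    for condition in config.conditions:
        expression[("species1", condition)] = simulate_expression(
            genes1, config, f"scion-{condition}", rng)
        expression[("species2", condition)] = simulate_expression(
            genes2, config, f"rootstock-{condition}", rng)
    truth.expression = expression

    mobile_targets: dict[tuple[str, str], dict[str, float]] = {}
    for condition in config.conditions:
        if config.mobile_per_direction > 0:
            mobile_targets[(UPWARD, condition)] = _choose_mobile(
                genes2, expression[("species2", condition)], config, rng)
            mobile_targets[(DOWNWARD, condition)] = _choose_mobile(
                genes1, expression[("species1", condition)], config, rng)
        else:
            mobile_targets[(UPWARD, condition)] = {}
            mobile_targets[(DOWNWARD, condition)] = {}
            truth.mobile[(UPWARD, condition)] = {}
            truth.mobile[(DOWNWARD, condition)] = {}

    design = build_design(config)
    genomes = {"species1": exp1, "species2": exp2}
    genes = {"species1": genes1, "species2": genes2}
    reads = simulate_graft_reads(design, genomes, genes, expression,
                                 mobile_targets, config, rng, truth)
    sp1 = SpeciesData("species1", ref1, exp1, genes1)
    sp2 = SpeciesData("species2", ref2, exp2, genes2)
    return Experiment(config=config, species1=sp1, species2=sp2,
                      design=design, reads=reads, truth=truth,
                      mobile_targets=mobile_targets)


def resimulate_reads(
    exp: Experiment,
    seed: int,
    fragments_per_library: int | None = None,
) -> tuple[dict[str, list[ReadRecord]], TruthSet]:
    """Redraw only the sequencing layer of an existing experiment.

    Genomes, gene models, expression and mobile targets stay fixed (they are
    properties of the study, not of a sequencing run); read sampling and
    errors are redrawn from ``seed``.  Used for replicated null experiments
    where re-simulating the genome would only re-test determinism.
    """
    from dataclasses import replace

    cfg = replace(exp.config, seed=seed,
                  fragments_per_library=(fragments_per_library
                                         or exp.config.fragments_per_library))
    rng = np.random.default_rng(seed)
    truth = TruthSet(expression=exp.truth.expression)
    genomes = {"species1": exp.species1.experimental,
               "species2": exp.species2.experimental}
    genes = {"species1": exp.species1.genes, "species2": exp.species2.genes}
    reads = simulate_graft_reads(exp.design, genomes, genes,
                                 exp.truth.expression, exp.mobile_targets,
                                 cfg, rng, truth)
    return reads, truth


def write_experiment(exp: Experiment, outdir: str | Path) -> None:
    """Dump an experiment to disk: FASTA, GFF3, FASTQ, truth TSVs, config echo."""
    import pandas as pd
    from .variants import write_variant_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in (exp.species1, exp.species2):
        sp.reference.to_fasta(outdir / f"{sp.name}_reference.fasta")
        sp.experimental.to_fasta(outdir / f"{sp.name}_experimental.fasta")
        write_gff3(sp.genes, outdir / f"{sp.name}_genes.gff3")
        write_variant_table(exp.truth.genotype_variants[sp.name],
                            outdir / f"{sp.name}_truth_variants.tsv")
    for lib_id, reads in exp.reads.items():
        write_fastq(reads, outdir / f"{lib_id}.fastq")
    mobile_rows = [
        {"direction": d, "condition": c, "gene_id": g,
         "transmission_fraction": f}
        for (d, c), table in sorted(exp.truth.mobile.items())
        for g, f in sorted(table.items())
    ]
    pd.DataFrame(mobile_rows, columns=["direction", "condition", "gene_id",
                                       "transmission_fraction"]
                 ).to_csv(outdir / "truth_mobile.tsv", sep="\t", index=False)
    expr_rows = [
        {"species": sp, "condition": c, "gene_id": g, "level": v}
        for (sp, c), table in sorted(exp.truth.expression.items())
        for g, v in sorted(table.items())
    ]
    pd.DataFrame(expr_rows).to_csv(outdir / "truth_expression.tsv",
                                   sep="\t", index=False)
    prov_rows = [
        {"library_id": lib, "read_id": rid, "origin_species": p.origin_species,
         "gene_id": p.gene_id, "mobile": p.mobile}
        for lib, table in sorted(exp.truth.provenance.items())
        for rid, p in sorted(table.items())
    ]
    pd.DataFrame(prov_rows).to_csv(outdir / "truth_provenance.tsv",
                                   sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(exp.config.echo(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------- evaluation
@dataclass
class CallEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None


def evaluate_calls(called: set[str], truth_mobile: set[str],
                   universe: set[str]) -> CallEvaluation:
    """Confusion-matrix scoring of a call set against planted truth.

    Undefined ratios (empty denominators) are returned as ``None`` markers,
    never as 0.
    """
    if not called <= universe:
        raise ValueError("called genes must be a subset of the gene universe")
    tp = len(called & truth_mobile)
    fp = len(called - truth_mobile)
    fn = len(truth_mobile - called)
    tn = len(universe) - tp - fp - fn
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = (2 * precision * recall / (precision + recall)
          if precision is not None and recall is not None
          and (precision + recall) > 0 else None)
    return CallEvaluation(tp=tp, fp=fp, fn=fn, tn=tn,
                          precision=precision, recall=recall, f1=f1)
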