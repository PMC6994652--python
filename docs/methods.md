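# Methods

## Model of the measurement

A heterograft experiment produces, per condition, four library roles with at
least two biological replicates each: heterograft scion, heterograft
rootstock, and the two homograft controls. A transcript of donor gene *g* is
*mobile* if it is produced in the donor tissue and a fraction of its
transcript pool (the **transmission fraction**) appears in the recipient
tissue's RNA population. Detection reduces to classifying each recipient
read as resident or foreign and deciding, per donor gene, whether the
foreign evidence is attributable to transport rather than to (i) the
genotype gap between the grafted plant and the published reference assembly
or (ii) cross-species homology. The pipeline addresses (i) by reference
correction and (ii) by homograft subtraction, on the grounds that a
homograft has no foreign partner and therefore any "foreign" signal it
shows is a cross-mapping artefact.

## Stage 1 — reference correction (`refmod`)

Resequencing reads are aligned with the built-in gapped mode (exact 31-mer
seeding, edit-distance extension within a ±16 bp window). When the optimal
edit path contains indels, the read is realigned with affine gap scores
(match +2, mismatch −4, gap open −8, extend −1, free end gaps on the
reference window): unit-cost alignment is ambiguous about gap placement and
splits contiguous indels into equal-cost fragments, which a pileup caller
cannot aggregate. Indel observations are left-aligned to the VCF normal
form before support counting.

The caller emits one candidate per (contig, position, alt allele) with:

* **SNP depth** — reads covering the column; **support** — reads showing the
  alternative base.
* **Indel depth** — reads spanning the indel junction with ≥ 4 aligned bases
  of flank on each side plus the indel length. An edit-distance aligner
  represents a short tail across an indel as mismatches, so tail reads can
  neither support nor refute the event and are excluded from its
  denominator.
* **Quality** — mean phred quality of the supporting observations; reads
  without qualities are assumed Q30 so FASTA-derived simulated reads pass
  the quality filter. Variants imported from VCF use `QUAL` directly.

Filters (defaults, all configurable): depth ≥ 6, alt fraction ≥ 0.9
("homozygous" operationalised as a consensus-caller-style zygosity
fraction), quality strictly > 20. Application is per contig in coordinate
order; overlapping variants keep the first by coordinate and report the
rest in a rejects list; a reference-allele mismatch is a hard error. The
returned `CoordinateMap` stores anchor pairs after each applied indel and
provides monotone forward/backward lift-over (positions inside deleted
intervals map to the last surviving base).

Reads the reference cannot place are assembled by a de Bruijn unitig
builder (k = 31, non-branching path compaction, reverse-complement
collapse, minimum scaffold length 200 bp) and appended as `scaffold_*`
contigs. This is an interface-level assembler: scaffold quality is not the
method's contribution, and real assembler output can be substituted.
Contaminant screening is a user-supplied exclusion-id list rather than a
remote database search.

## Stage 2 — detection (`readclass`, `mobilecall`, `pipeline`)

Resident mapping uses the ungapped matcher with a 5% mismatch budget; the
unmapped remainder is matched against both corrected genomes with a 30%
budget, reflecting that a similarity search is far more permissive than
end-to-end mapping. Hits shorter than 50 bases fail the gate (as does any
hit whose source reports an e-value above 1e−5). A fragment (read pair
collapsed by id; at desk scale the simulator emits single-end reads, which
under this collapse are equivalent) is foreign when its best foreign score
beats its best own-genome score; exact ties are discarded as ambiguous —
the conservative choice against homolog-driven false positives. Foreign
fragments increment the donor gene whose exons they overlap most
(ties → lexicographically smallest id).

Per direction and replicate, the call rule is:
`A-count(g) > 0` ∧ `g ∉ B` ∧ `g ∉ C` ∧ `foreign-FPKM(g) > 0.05`, where

* **B** is the union over homograft-control replicates of genes with any
  control foreign fragment (stringent gene-level subtraction, default; a
  lenient mode subtracts only when control foreign FPKM > 0.05);
* **C** is the complement of the donor-tissue expressed set, "expressed"
  meaning FPKM > 0.05 in ≥ 1 donor replicate (the same threshold reused for
  internal consistency; an all-replicates mode exists);
* foreign FPKM is computed from the A-counts against the recipient
  library's resident-mapped fragment total — the standard per-library
  depth normaliser.

Final calls are the intersection across all replicates; the FPKM threshold
is enforced per replicate (the stricter of the two possible readings).
Single-replicate inputs are an error unless explicitly permitted.

## The simulator (`graftsim`)

The generator emulates the structure of the real study, not its scale:

| parameter | default | rationale |
|---|---|---|
| genome | 2 contigs × 200 kb/species | desk-scale whole-pipeline runs |
| genes | 200/species, single-exon, 0.6–1.8 kb | transcripts are simulated unspliced and the matcher is unspliced, so exon structure is orthogonal here; multi-exon models are supported downstream |
| interspecies divergence | 10% SNP + 0.5% indel (≤ 10 bp) | congeneric-distance homology; species 2 is *derived* from species 1 so every gene has a liftable homolog, which is what makes cross-mapping a real failure mode |
| genotype layer | 500 SNPs + 50 ins + 50 del per genome, ≥ 100 bp apart, plus 2 × 1 kb genotype-specific segments | a realistic within-species gap; spacing keeps planted edits independent |
| expression | log-normal (median 5, σ 1.5), 30% unexpressed | typical bulk RNA-seq dispersion; the unexpressed fraction feeds the C sets |
| libraries | 50k single-end 100 bp fragments, 1% error, 2 replicates | smallest scale at which the per-replicate FPKM logic is exercised in minutes |
| mobility | 20 genes/direction, planted foreign FPKM log-uniform in 200–2000 | see below |

Mobile genes are drawn from donor genes with expression ≥ 1; the
transmission fraction is derived from a target foreign FPKM
(`f = φ·W_resident/(10⁹·e_donor)`, capped at 1), which keeps mobility
uncorrelated with donor abundance above the floor while pinning the
*detectability* of planted genes. The planted range 200–2000 FPKM is the
desk-scale equivalent of the sub-5-FPKM regime at production depth: at 50k
fragments/library it corresponds to ≈ 10–100 expected foreign reads per
gene, exactly the read-count regime a >400M-read study probes at FPKM
0.05–5 (an FPKM of 0.2 at 50k fragments would be 0.01 expected reads —
undetectable by construction at any precision).

What the simulator does **not** model: splicing and junction reads, GC and
positional bias, PCR duplicates, condition-dependent differential
expression, indel sequencing errors. Passing tests therefore demonstrate
the correctness of the classification and set logic under honest homology
and error, not robustness to every artefact of real libraries.

Determinism: all randomness flows from one integer seed through a single
`numpy` generator in a fixed order; identical configurations give
byte-identical FASTA/FASTQ/TSV outputs on any platform.

## Validation arithmetic (`physiol`)

`REC = (R1/R2) × 100` (R2 = post-boiling conductivity, must be positive;
R1 > R2 warns but computes). `2^−ΔΔCt` uses an explicit no-amplification
marker, never a sentinel cycle: a silent calibrator yields an infinite
ratio, a silent sample a below-detection 0. The mobility verdict is
*supported* when heterograft/control > 2-fold (configurable) or the control
is silent while the heterograft amplifies; *refuted* when the heterograft
is silent or the control matches it; *indeterminate* when both are silent —
the fold default makes the qualitative published rule operational.

## Numerical and design choices

* Tie-breaks are total and deterministic everywhere: alignment ties by
  (mismatches, contig, position, strand with + first); gene-assignment ties
  by gene id; equal cross-genome scores are discarded rather than assigned.
* Thresholds follow their stated inequalities exactly: depth ≥ 6 and
  zygosity ≥ 0.9 are inclusive, quality > 20 and FPKM > 0.05 strict.
* FPKM identity `Σ fpkm·(len/1000)·(total/10⁶) = Σ counts` is maintained to
  1e−6 relative and asserted in the test suite.
* Acceptance-scale problem sizes (full detection at 8 × 50k fragments; the
  zero-mobility null at 100 read-resamplings of 8 × 4k fragments over a
  fixed genome) are the package's chosen desk-scale study conditions; the
  null fixes the genome because a study's genome does not change between
  sequencing runs, and re-simulating it each run would only re-test seed
  determinism.

## Known limitations

* The built-in matcher is a desk-scale stand-in, not a replacement for a
  production aligner/similarity search; SAM and 12-column tabular hits from
  external tools plug in at the same module boundary.
* Genes on appended scaffolds participate in calling only if the user
  supplies models for them.
* Multi-allelic sites resolve to whichever allele passes the zygosity
  filter (at most one can); heterozygous variants are deliberately
  discarded, as the correction targets homozygous genotype differences.
* The B/C subtraction granularity (gene-level, stringent) is one of two
  defensible readings; both are implemented and the choice is a parameter.
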