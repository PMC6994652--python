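"""Reference correction: pileup calling, filtering, application, assembly."""

import numpy as np
import pytest

from mobigraft import (
    AlignmentRecord,
    GenomeSequence,
    ReadRecord,
    SequenceVariant,
    apply_variants,
    assemble_unmapped,
    build_modified_reference,
    call_pileup_variants,
    filter_variants,
)
from mobigraft.genome import GenomeError, reverse_complement
from mobigraft.graftsim import _random_sequence
from mobigraft.refmod import ScaffoldSet


def _aln(read_id, contig, pos, seq, cigar=None, quals=None):
    return AlignmentRecord(
        read_id=read_id, mapped=True, contig=contig, position=pos,
        aligned_length=len(seq), score=float(len(seq)), source="builtin",
        cigar=cigar or [("M", len(seq))], aligned_sequence=seq,
        aligned_qualities=quals,
    )


class TestCallPileupVariants:
    def test_unanimous_snp_column(self):
        ref = GenomeSequence("r", {"c": "AACAAAAAAA"})
        alns = [_aln(f"r{i}", "c", 1, "AATAAAAAAA") for i in range(10)]
        (v,) = call_pileup_variants(alns, ref)
        assert (v.contig, v.position, v.ref, v.alt) == ("c", 3, "C", "T")
        assert v.depth == 10 and v.alt_support == 10
        assert v.zygosity_fraction == 1.0

    def test_reference_matching_reads_emit_nothing(self):
        ref = GenomeSequence("r", {"c": "ACGTACGTAC"})
        alns = [_aln(f"r{i}", "c", 1, "ACGTACGTAC") for i in range(10)]
        assert call_pileup_variants(alns, ref) == []

    def test_mixed_column_reports_half_zygosity(self):
        ref = GenomeSequence("r", {"c": "AACAAAAAAA"})
        alns = [_aln(f"r{i}", "c", 1, "AATAAAAAAA") for i in range(5)]
        alns += [_aln(f"s{i}", "c", 1, "AACAAAAAAA") for i in range(5)]
        (v,) = call_pileup_variants(alns, ref)
        assert v.depth == 10 and v.alt_support == 5
        assert v.zygosity_fraction == 0.5
        assert filter_variants([v]) == []

    def test_unknown_contig_is_hard_error(self):
        ref = GenomeSequence("r", {"c": "ACGT" * 5})
        with pytest.raises(GenomeError, match="nope"):
            call_pileup_variants([_aln("r1", "nope", 1, "ACGT" * 5)], ref)

    def test_out_of_bounds_is_hard_error(self):
        ref = GenomeSequence("r", {"c": "ACGTACGT"})
        with pytest.raises(GenomeError, match="out of bounds|past end"):
            call_pileup_variants([_aln("r1", "c", 5, "ACGTACGT")], ref)

    def test_deletion_called_from_cigar(self):
        # reference AAAACGTTTTCC, reads lack CGT -> deletion anchored at pos 4
        ref = GenomeSequence("r", {"c": "AAAACGTTTTCC"})
        cigar = [("M", 4), ("D", 3), ("M", 5)]
        alns = [_aln(f"r{i}", "c", 1, "AAAATTTCC", cigar=cigar) for i in range(8)]
        (v,) = call_pileup_variants(alns, ref)
        assert (v.position, v.ref, v.alt, v.kind) == (4, "ACGT", "A", "DEL")
        assert v.alt_support == 8

    def test_insertion_called_and_left_aligned(self):
        # insertion of T into a T homopolymer must anchor left of the run
        ref = GenomeSequence("r", {"c": "AACGTTTTACGTT"})
        cigar = [("M", 6), ("I", 1), ("M", 7)]
        alns = [_aln(f"r{i}", "c", 1, "AACGTTTTTACGTT", cigar=cigar)
                for i in range(6)]
        (v,) = call_pileup_variants(alns, ref)
        assert v.kind == "INS"
        assert (v.position, v.ref, v.alt) == (4, "G", "GT")


class TestFilterVariants:
    @pytest.mark.parametrize(
        "depth,support,quality,kept",
        [
            (5, 5, 40.0, False),   # below the >=6 reads rule
            (6, 6, 21.0, True),    # minimal passing candidate
            (6, 6, 20.0, False),   # quality must be strictly > 20
            (10, 8, 40.0, False),  # 0.8 < 0.9 homozygosity fraction
            (10, 9, 40.0, True),
        ],
    )
    def test_filter_boundaries(self, depth, support, quality, kept):
        v = SequenceVariant("c", 10, "A", "T", depth=depth,
                            alt_support=support, quality=quality)
        assert (filter_variants([v]) == [v]) is kept

    def test_empty_in_empty_out_and_order_preserved(self):
        assert filter_variants([]) == []
        vs = [SequenceVariant("c", p, "A", "T", depth=10, alt_support=10,
                              quality=30.0) for p in (30, 10, 20)]
        assert filter_variants(vs) == vs


def _naive_edit_oracle(seq: str, variants):
    """Independent right-to-left string-edit application."""
    for v in sorted(variants, key=lambda v: -v.position):
        start = v.position - 1
        assert seq[start : start + len(v.ref)] == v.ref
        seq = seq[:start] + v.alt + seq[start + len(v.ref):]
    return seq


class TestApplyVariants:
    def test_noop_returns_identical_sequence(self, toy_genome):
        result = apply_variants(toy_genome, [])
        assert result.genome.contigs == toy_genome.contigs
        assert result.genome.role == "modified"
        for contig in toy_genome.contigs:
            assert result.coordinate_map.forward(contig, 3) == 3

    def test_single_snp(self):
        genome = GenomeSequence("g", {"c": "ACGT"})
        result = apply_variants(genome, [SequenceVariant("c", 2, "C", "T")])
        assert result.genome.contigs["c"] == "ATGT"
        assert genome.contigs["c"] == "ACGT"  # input untouched

    def test_matches_string_edit_oracle(self, rng):
        """3 insertions (+7 bases) and 2 deletions (-4) on a 1 kb contig."""
        seq = _random_sequence(rng, 1000)
        genome = GenomeSequence("g", {"c": seq})
        variants = [
            SequenceVariant("c", 100, seq[99], seq[99] + "AC"),
            SequenceVariant("c", 300, seq[299], seq[299] + "GGG"),
            SequenceVariant("c", 500, seq[499], seq[499] + "TT"),
            SequenceVariant("c", 700, seq[699] + seq[700:703], seq[699]),
            SequenceVariant("c", 900, seq[899] + seq[900], seq[899]),
        ]
        result = apply_variants(genome, variants)
        assert len(result.genome.contigs["c"]) == 1003
        assert result.genome.contigs["c"] == _naive_edit_oracle(seq, variants)

    def test_length_conservation_on_random_variants(self, rng):
        seq = _random_sequence(rng, 5000)
        genome = GenomeSequence("g", {"c": seq})
        variants = []
        for pos in range(50, 4900, 61):
            anchor = seq[pos - 1]
            kind = int(rng.integers(0, 3))
            if kind == 0:
                alt = "ACGT"[("ACGT".index(anchor) + 1) % 4]
                variants.append(SequenceVariant("c", pos, anchor, alt))
            elif kind == 1:
                ins = _random_sequence(rng, int(rng.integers(1, 9)))
                variants.append(SequenceVariant("c", pos, anchor, anchor + ins))
            else:
                d = int(rng.integers(1, 9))
                variants.append(
                    SequenceVariant("c", pos, anchor + seq[pos : pos + d], anchor))
        result = apply_variants(genome, variants)
        expected_delta = sum(v.length_change for v in result.applied)
        assert len(result.genome.contigs["c"]) == 5000 + expected_delta
        assert result.genome.contigs["c"] == _naive_edit_oracle(
            seq, result.applied)

    def test_reference_mismatch_is_hard_error(self):
        genome = GenomeSequence("g", {"c": "ACGT"})
        with pytest.raises(GenomeError, match="c:2"):
            apply_variants(genome, [SequenceVariant("c", 2, "G", "T")])

    def test_overlapping_variant_skipped_with_report(self):
        genome = GenomeSequence("g", {"c": "AACGTTTT"})
        first = SequenceVariant("c", 2, "ACG", "A")  # deletes CG
        second = SequenceVariant("c", 3, "C", "T")  # inside the deletion
        result = apply_variants(genome, [second, first])
        assert result.applied == [first]
        assert result.rejected == [second]
        assert result.genome.contigs["c"] == "AATTTT"


class TestAssembleUnmapped:
    def test_no_reads_gives_empty_set(self):
        out = assemble_unmapped([])
        assert out.scaffolds.contigs == {}

    def test_k_exceeding_read_length_warns_and_returns_empty(self, caplog):
        reads = [ReadRecord("r1", "ACGT" * 5)]
        with caplog.at_level("WARNING"):
            out = assemble_unmapped(reads, k=31)
        assert out.scaffolds.contigs == {}
        assert "exceeds" in caplog.text

    def test_reconstructs_source_from_tiling_reads(self, rng):
        """Error-free reads tiling a repeat-free 500 bp source give one unitig."""
        while True:
            source = _random_sequence(rng, 500)
            kmers = {source[i : i + 31] for i in range(len(source) - 30)}
            rc = reverse_complement(source)
            kmers_rc = {rc[i : i + 31] for i in range(len(rc) - 30)}
            if len(kmers) == 470 and not (kmers & kmers_rc):
                break
        reads = [ReadRecord(f"r{i}", source[i : i + 80])
                 for i in range(0, 421, 20)]
        out = assemble_unmapped(reads, k=31, min_scaffold_len=200)
        (unitig,) = out.scaffolds.contigs.values()
        assert unitig in (source, reverse_complement(source))

    def test_unitigs_stop_at_repeated_kmer(self):
        """A repeated k-mer is a branch point: no chimeric join across it."""
        k = 5
        core = "AAGGG"  # appears twice with different continuations
        seq = "TACGT" + core + "CTTAG" + core + "GATCA"
        reads = [ReadRecord(f"r{i}", seq[i : i + 12]) for i in range(len(seq) - 11)]
        out = assemble_unmapped(reads, k=k, min_scaffold_len=6)
        for unitig in out.scaffolds.contigs.values():
            assert seq not in (unitig, reverse_complement(unitig))


class TestBuildModifiedReference:
    def test_zero_inputs_copies_with_modified_role(self, toy_genome):
        result = build_modified_reference(toy_genome, [], None)
        assert result.genome.contigs == toy_genome.contigs
        assert result.genome.role == "modified"

    def test_excluded_scaffold_is_dropped(self, toy_genome):
        scaffolds = ScaffoldSet(
            scaffolds=GenomeSequence("s", {"scaffold_00001": "ACGT" * 100},
                                     role="scaffold-extra"))
        result = build_modified_reference(toy_genome, [], scaffolds,
                                          {"scaffold_00001"})
        assert set(result.genome.contigs) == set(toy_genome.contigs)

    def test_scaffold_arithmetic(self, toy_genome):
        contigs = {f"scaffold_{i:05d}": _random_sequence(
            np.random.default_rng(i), 300) for i in range(1, 4)}
        scaffolds = ScaffoldSet(
            scaffolds=GenomeSequence("s", contigs, role="scaffold-extra"))
        result = build_modified_reference(toy_genome, [], scaffolds,
                                          {"scaffold_00002"})
        assert len(result.genome.contigs) == 4  # 2 contigs + 3 scaffolds - 1

    def test_id_collision_is_hard_error(self):
        genome = GenomeSequence("g", {"scaffold_00001": "ACGT" * 10})
        clash = ScaffoldSet(
            scaffolds=GenomeSequence("s", {"scaffold_00001": "ACGT" * 100},
                                     role="scaffold-extra"))
        with pytest.raises(GenomeError, match="collides"):
            build_modified_reference(genome, [], clash)
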