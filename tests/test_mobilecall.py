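"""FPKM quantification and the mobile-call set logic."""

import numpy as np
import pytest

from mobigraft import (
    CandidateEvidence,
    call_mobile_replicate,
    compute_fpkm,
    expressed_gene_set,
    intersect_replicates,
    low_expression_fraction,
    summarize_calls,
)
from mobigraft.mobilecall import ExpressionRecord, GraftDesign, SampleLibrary
from conftest import make_gene


def _genes(lengths: dict[str, int]):
    return [make_gene(g, "c", [(1, n)]) for g, n in lengths.items()]


class TestComputeFpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (10, 1000, 1_000_000, 10.0),
            (0, 1000, 1_000_000, 0.0),
            (1, 2000, 4_000_000, 0.125),
        ],
    )
    def test_definition(self, count, length, total, expected):
        (rec,) = compute_fpkm({"g": count}, _genes({"g": length}), total)
        assert rec.fpkm == pytest.approx(expected)

    def test_missing_gene_model_is_hard_error(self):
        with pytest.raises(KeyError, match="ghost"):
            compute_fpkm({"ghost": 3}, _genes({"g": 100}), 1000)

    def test_normalization_identity(self, rng):
        """Sum of fpkm x len_kb x totalM recovers the raw count sum."""
        lengths = {f"g{i}": int(l) for i, l in
                   enumerate(rng.integers(200, 5000, size=50))}
        counts = {g: int(c) for g, c in
                  zip(lengths, rng.integers(0, 500, size=50))}
        total = 750_000
        recs = compute_fpkm(counts, _genes(lengths), total)
        recovered = sum(r.fpkm * (lengths[r.gene_id] / 1000) * (total / 1e6)
                        for r in recs)
        assert recovered == pytest.approx(sum(counts.values()), rel=1e-9)


class TestExpressedGeneSet:
    def _rec(self, gene, fpkm, lib="L1"):
        return ExpressionRecord(gene, lib, 1 if fpkm > 0 else 0, fpkm)

    def test_strictly_above_threshold(self):
        expr = [self._rec("a", 0.06), self._rec("b", 0.05), self._rec("c", 0.0)]
        assert expressed_gene_set(expr) == {"a"}

    def test_any_vs_all_replicate_modes(self):
        expr = [self._rec("a", 0.2, "L1"), self._rec("a", 0.0, "L2"),
                self._rec("b", 0.2, "L1"), self._rec("b", 0.3, "L2")]
        assert expressed_gene_set(expr, mode="any-replicate") == {"a", "b"}
        assert expressed_gene_set(expr, mode="all-replicates") == {"b"}

    def test_empty_table_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert expressed_gene_set([]) == set()
        assert "empty" in caplog.text


class TestCallMobileReplicate:
    def test_set_subtraction_example(self):
        genes = _genes({"g1": 1000, "g2": 1000})
        evidence = CandidateEvidence("upward", "24C", 1,
                                     a_counts={"g1": 8, "g2": 5},
                                     b_genes={"g2"}, c_genes=set())
        calls = call_mobile_replicate(evidence, genes, 1_000_000)
        assert set(calls) == {"g1"}
        assert calls["g1"] == pytest.approx(8.0)

    def test_donor_unexpressed_gene_excluded(self):
        genes = _genes({"g3": 1000})
        evidence = CandidateEvidence("upward", "24C", 1,
                                     a_counts={"g3": 100},
                                     b_genes=set(), c_genes={"g3"})
        assert call_mobile_replicate(evidence, genes, 1_000_000) == {}

    def test_fpkm_threshold_strict(self):
        genes = _genes({"g": 1000})
        evidence = CandidateEvidence("upward", "24C", 1, {"g": 1},
                                     set(), set())
        # count 1, 1 kb, 20M fragments -> FPKM 0.05 exactly: excluded
        assert call_mobile_replicate(evidence, genes, 20_000_000) == {}
        # 19,999,999 fragments -> just above 0.05: included
        assert set(call_mobile_replicate(evidence, genes, 19_999_999)) == {"g"}

    def test_matches_brute_force_rule_oracle(self, rng):
        """1,000 random instances against direct per-gene rule evaluation."""
        gene_ids = [f"g{i}" for i in range(30)]
        for _ in range(1_000):
            lengths = {g: int(l) for g, l in
                       zip(gene_ids, rng.integers(150, 4000, size=30))}
            a = {g: int(c) for g, c in zip(gene_ids, rng.integers(0, 6, size=30))}
            b = {g for g in gene_ids if rng.random() < 0.3}
            c = {g for g in gene_ids if rng.random() < 0.3}
            total = int(rng.integers(10_000, 50_000_000))
            min_fpkm = float(rng.choice([0.05, 0.5, 5.0]))
            evidence = CandidateEvidence("upward", "x", 1, a, b, c)
            got = call_mobile_replicate(evidence, _genes(lengths), total,
                                        min_fpkm=min_fpkm)
            expected = {}
            for g in gene_ids:  # independent re-statement of the rule
                if a[g] <= 0 or g in b or g in c:
                    continue
                fpkm = a[g] / (lengths[g] / 1000.0) / (total / 1e6)
                if fpkm > min_fpkm:
                    expected[g] = fpkm
            assert got == expected

    def test_monotonicity_in_controls_and_threshold(self, rng):
        genes = _genes({f"g{i}": 1000 for i in range(20)})
        a = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 10, size=20))}
        base = CandidateEvidence("upward", "x", 1, a, {"g1"}, {"g2"})
        calls = set(call_mobile_replicate(base, genes, 100_000))
        bigger_b = CandidateEvidence("upward", "x", 1, a, {"g1", "g5"}, {"g2"})
        assert set(call_mobile_replicate(bigger_b, genes, 100_000)) <= calls
        stricter = set(call_mobile_replicate(base, genes, 100_000, min_fpkm=50.0))
        assert stricter <= calls


class TestIntersectReplicates:
    def test_pairwise_intersection(self):
        assert intersect_replicates([{"g1", "g2"}, {"g2", "g3"}]) == {"g2"}

    def test_idempotent_and_disjoint(self):
        assert intersect_replicates([{"a", "b"}, {"a", "b"}]) == {"a", "b"}
        assert intersect_replicates([{"a"}, {"b"}]) == set()

    def test_single_replicate_requires_explicit_flag(self, caplog):
        with pytest.raises(ValueError, match="2 replicates"):
            intersect_replicates([{"a"}])
        with caplog.at_level("WARNING"):
            assert intersect_replicates([{"a"}], allow_single=True) == {"a"}
        assert "NOT replicate-supported" in caplog.text


class TestSummarizeCalls:
    def test_shared_and_exclusive_counts(self):
        calls = {("upward", "24C"): {"a", "b", "c"},
                 ("upward", "6C"): {"b", "c", "d", "e"}}
        s = summarize_calls(calls)
        assert s.per_direction_condition[("upward", "24C")] == 3
        assert s.shared[("upward", "24C", "6C")] == 2
        assert s.exclusive[("upward", "24C")] == 1
        assert s.exclusive[("upward", "6C")] == 2
        # conservation: exclusive + shared = condition total
        assert s.exclusive[("upward", "24C")] + s.shared[("upward", "24C", "6C")] == 3

    def test_identical_and_empty_sides(self):
        same = summarize_calls({("down", "a"): {"x"}, ("down", "b"): {"x"}})
        assert same.shared[("down", "a", "b")] == 1
        assert same.exclusive[("down", "a")] == 0
        empty = summarize_calls({("down", "a"): set(), ("down", "b"): {"x"}})
        assert empty.shared[("down", "a", "b")] == 0


class TestLowExpressionFraction:
    def _expr(self, table, lib="L1"):
        return [ExpressionRecord(g, lib, 1 if f > 0 else 0, f)
                for g, f in table.items()]

    def test_all_below_cutoff(self):
        expr = self._expr({"a": 0.2, "b": 0.5})
        assert low_expression_fraction({"a", "b"}, expr) == 1.0

    def test_half_below(self):
        expr = self._expr({"a": 0.2, "b": 0.5, "c": 3.0, "d": 2.0})
        assert low_expression_fraction({"a", "b", "c", "d"}, expr) == 0.5

    def test_empty_mobile_set_is_undefined(self):
        assert low_expression_fraction(set(), self._expr({"a": 1.0})) is None

    def test_matches_recount_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        expr = []
        means = {}
        for g in genes:
            vals = rng.lognormal(0, 1.5, size=2)
            means[g] = float(np.mean(vals))
            expr += [ExpressionRecord(g, f"L{j}", 1, float(v))
                     for j, v in enumerate(vals)]
        mobile = set(rng.choice(genes, size=15, replace=False))
        got = low_expression_fraction(mobile, expr, cutoff=1.0)
        expected = sum(means[g] < 1.0 for g in mobile) / len(mobile)
        assert got == pytest.approx(expected)


class TestGraftDesign:
    def test_missing_control_role_is_hard_error(self):
        libs = [
            SampleLibrary("l1", "A/B", "scion", "24C", 1),
            SampleLibrary("l2", "A/B", "scion", "24C", 2),
            SampleLibrary("l3", "A/B", "rootstock", "24C", 1),
            SampleLibrary("l4", "A/B", "rootstock", "24C", 2),
        ]
        design = GraftDesign("A", "B", libs)
        with pytest.raises(ValueError, match="homograft"):
            design.validate()

    def test_role_derivation(self):
        hetero = SampleLibrary("l1", "A/B", "scion", "24C", 1)
        homo = SampleLibrary("l2", "B/B", "rootstock", "24C", 1)
        design = GraftDesign("A", "B", [hetero, homo])
        assert design.role_of(hetero) == "heterograft-scion"
        assert design.role_of(homo) == "homograft-rootstock"
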