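"""Pairwise SNP detection and the non-redundant genotype matrix."""

import numpy as np
import pytest

from snpmine.consensus import CallStatus, ConsensusCall
from snpmine.seqio import ReferenceSequence
from snpmine.snpcall import (
    build_snp_matrix,
    pairwise_count_table,
    pairwise_snps,
    snps_vs_reference,
)

REF = [ReferenceSequence("chr1", "ACGTACGTAC" * 10)]


def cc(pos, call, status=None, ref_id="chr1", depth=10):
    if status is None:
        status = CallStatus.MAJOR if call in "ACGT" else CallStatus.HETEROZYGOUS
    ratio = 1.0 if status is CallStatus.MAJOR else 0.5
    return ConsensusCall(ref_id=ref_id, pos=pos, call=call,
                         confidence_ratio=ratio, depth=depth, status=status)


def calls_of(symbols_by_pos, ref_id="chr1"):
    return {ref_id: {pos: cc(pos, sym) for pos, sym in symbols_by_pos.items()}}


class TestPairwise:
    def test_differing_major_calls_are_snps(self):
        assert pairwise_snps(calls_of({5: "A"}), calls_of({5: "G"})) == [("chr1", 5)]

    def test_identical_calls_are_not(self):
        assert pairwise_snps(calls_of({5: "A"}), calls_of({5: "A"})) == []

    def test_missing_in_either_never_reports(self):
        assert pairwise_snps(calls_of({5: "A"}), calls_of({})) == []
        m = {"chr1": {5: ConsensusCall("chr1", 5, "-", 0.0, 1, CallStatus.MISSING)}}
        assert pairwise_snps(calls_of({5: "A"}), m) == []

    def test_heterozygote_vs_major_strict_and_lenient(self):
        a, r = calls_of({5: "A"}), calls_of({5: "R"})
        # strict ignores heterozygotes; lenient suppresses nested sets (A in R)
        assert pairwise_snps(a, r, "strict") == []
        assert pairwise_snps(a, r, "lenient") == []

    def test_disjoint_heterozygotes_lenient_only(self):
        r, y = calls_of({5: "R"}), calls_of({5: "Y"})
        assert pairwise_snps(r, y, "strict") == []
        assert pairwise_snps(r, y, "lenient") == [("chr1", 5)]

    def test_symmetry(self, rng):
        def random_calls():
            return calls_of({
                int(p): str(rng.choice(list("ACGTRYSWKM")))
                for p in rng.choice(100, size=30, replace=False) + 1
            })
        for mode in ("strict", "lenient"):
            a, b = random_calls(), random_calls()
            assert pairwise_snps(a, b, mode) == pairwise_snps(b, a, mode)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pairwise_snps(calls_of({}), calls_of({}), "fuzzy")


class TestVsReference:
    def test_examples(self):
        # reference base at pos 5 is 'A' (ACGTACGTAC pattern)
        assert snps_vs_reference(calls_of({5: "G"}), REF) == [("chr1", 5)]
        assert snps_vs_reference(calls_of({5: "A"}), REF) == []

    def test_reference_n_excluded(self):
        ref_n = [ReferenceSequence("chr1", "ANGT")]
        assert snps_vs_reference(calls_of({2: "G"}), ref_n) == []


class TestMatrix:
    def two_sample_calls(self):
        # sample1 matches the reference; sample2 differs at 5 positions
        ref = REF[0].bases
        s1 = calls_of({p: ref[p - 1] for p in range(1, 21)})
        diff = {5: "G", 8: "C", 12: "T", 15: "G", 18: "A"}
        s2_symbols = {p: ref[p - 1] for p in range(1, 21)}
        for p, alt in diff.items():
            assert ref[p - 1] != alt
            s2_symbols[p] = alt
        return {"sample1": s1, "sample2": calls_of(s2_symbols)}, diff

    def test_union_of_pairwise_and_vs_reference(self):
        all_calls, diff = self.two_sample_calls()
        matrix = build_snp_matrix(all_calls, REF)
        assert matrix.locus_set() == {("chr1", p) for p in diff}
        assert matrix.samples[0] == "Reference"

    def test_completeness_and_non_redundancy(self, rng):
        def random_calls():
            return calls_of({
                int(p): str(rng.choice(list("ACGT")))
                for p in rng.choice(90, size=40, replace=False) + 1
            })
        all_calls = {f"s{i}": random_calls() for i in range(4)}
        matrix = build_snp_matrix(all_calls, REF)
        # oracle: independent union over every comparison
        expected = set()
        names = list(all_calls)
        for n in names:
            expected |= set(snps_vs_reference(all_calls[n], REF))
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                expected |= set(pairwise_snps(all_calls[a], all_calls[b]))
        assert matrix.locus_set() == expected
        assert len(matrix.loci) == len(set(matrix.loci))  # non-redundant
        assert [tuple(l[:2]) for l in matrix.loci] == sorted(matrix.locus_set())

    def test_snp_only_vs_reference_included(self):
        # both samples agree on a non-reference base
        s = calls_of({5: "G"})
        matrix = build_snp_matrix({"s1": s, "s2": s}, REF)
        assert matrix.locus_set() == {("chr1", 5)}
        row = matrix.row("chr1", 5)
        assert row == ["A", "G", "G"]

    def test_no_variation_empty_matrix(self):
        s = calls_of({5: "A"})
        matrix = build_snp_matrix({"s1": s, "s2": s}, REF)
        assert matrix.loci == [] and matrix.alleles == []

    def test_missing_symbol_in_matrix(self):
        all_calls = {"s1": calls_of({5: "G"}), "s2": calls_of({})}
        matrix = build_snp_matrix(all_calls, REF)
        assert matrix.row("chr1", 5) == ["A", "G", "-"]


class TestCountTable:
    def test_matches_direct_counts(self):
        ref = REF[0].bases
        s1 = calls_of({p: ref[p - 1] for p in range(1, 21)})
        s2_symbols = {p: ref[p - 1] for p in range(1, 21)}
        for p, alt in {5: "G", 8: "C", 12: "T"}.items():
            s2_symbols[p] = alt
        all_calls = {"s1": s1, "s2": calls_of(s2_symbols)}
        table = pairwise_count_table(all_calls, REF)
        assert table.loc["s1", "s2"] == 3
        assert table.loc["s2", "s1"] == 3
        assert table.loc["Reference", "s2"] == 3
        assert table.loc["Reference", "s1"] == 0
        assert (np.diag(table.values) == 0).all()
        assert (table.values == table.values.T).all()

    def test_single_sample_vs_reference_only(self):
        table = pairwise_count_table({"s1": calls_of({5: "G"})}, REF)
        assert table.shape == (2, 2)
        assert table.loc["Reference", "s1"] == 1

    def test_all_missing_sample_zero_row(self):
        table = pairwise_count_table(
            {"s1": calls_of({5: "G"}), "s2": calls_of({})}, REF
        )
        assert table.loc["s2"].sum() == 0
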