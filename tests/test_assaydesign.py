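"""Assay suitability screening and KASP/ADT/GFF3 writers."""

import numpy as np
import pytest

from snpmine.assaydesign import (
    AssayParams,
    extract_flanks,
    screen_candidate,
    screen_matrix,
    write_adt_input,
    write_gff3_snps,
    write_kasp_input,
)
from snpmine.seqio import ReferenceSequence
from snpmine.snpcall import SnpMatrix

PARAMS = AssayParams()


def random_reference(rng, length=1000, seq_id="chr1"):
    return ReferenceSequence(seq_id, "".join(rng.choice(list("ACGT"), size=length)))


class TestExtractFlanks:
    def test_too_close_to_start(self, rng):
        ref = [random_reference(rng, 200)]
        assert extract_flanks(("chr1", 10), ref, 50) is None

    def test_interior_position(self, rng):
        ref = [random_reference(rng, 200)]
        left, right = extract_flanks(("chr1", 100), ref, 50)
        assert len(left) == len(right) == 50
        assert left == ref[0].bases[49:99]
        assert right == ref[0].bases[100:150]

    def test_too_close_to_end(self, rng):
        ref = [random_reference(rng, 200)]
        assert extract_flanks(("chr1", 151), ref, 50) is None

    def test_unknown_reference(self, rng):
        with pytest.raises(ValueError):
            extract_flanks(("chrX", 100), [random_reference(rng)], 50)


def designed_fixture(rng):
    """1 kb reference with 5 SNPs triggering each failure mode once.

    pos 500: clean pass; pos 10: incomplete flank; pos 200: N at 190 in its
    flank; pos 800 & 830: mutually co-sited.  Hand count: exactly 1 passes.
    """
    bases = list(random_reference(rng, 1000).bases)
    bases[189] = "N"  # 1-based 190
    ref = ReferenceSequence("chr1", "".join(bases))
    positions = [10, 200, 500, 800, 830]
    loci = [("chr1", p, ref.bases[p - 1]) for p in positions]
    alt = {p: next(b for b in "ACGT" if b != ref.bases[p - 1]) for p in positions}
    alleles = [[ref.bases[p - 1], ref.bases[p - 1], alt[p]] for p in positions]
    matrix = SnpMatrix(loci=loci, samples=["Reference", "s1", "s2"], alleles=alleles)
    return [ref], matrix


class TestScreening:
    @pytest.mark.parametrize("platform", ["KASP", "Illumina"])
    def test_each_failure_mode_once(self, rng, platform):
        ref, matrix = designed_fixture(rng)
        candidates = screen_matrix(matrix, ref, PARAMS, platform)
        by_pos = {c.locus[1]: c for c in candidates}
        assert by_pos[500].verdict == "pass"
        assert by_pos[10].fail_reasons == {"incomplete_flank"}
        assert by_pos[200].fail_reasons == {"ambiguous_base"}
        assert by_pos[800].fail_reasons == {"cosited_snp"}
        assert by_pos[830].fail_reasons == {"cosited_snp"}
        assert sum(1 for c in candidates if c.verdict == "pass") == 1

    def test_screening_is_idempotent(self, rng):
        ref, matrix = designed_fixture(rng)
        first = screen_matrix(matrix, ref, PARAMS, "KASP")
        second = screen_matrix(matrix, ref, PARAMS, "KASP")
        assert [(c.locus, c.fail_reasons) for c in first] == [
            (c.locus, c.fail_reasons) for c in second
        ]

    def test_nearby_snp_outside_flank_passes(self, rng):
        ref = [random_reference(rng, 1000)]
        loci = [("chr1", 400, ref[0].bases[399]), ("chr1", 461, ref[0].bases[460])]
        all_loci = {(r, p) for r, p, _ in loci}
        c = screen_candidate(loci[0], ["A", "A", "G"], ref, all_loci,
                             AssayParams(flank_len_kasp=50), "KASP")
        # nearest other SNP is 61 bp away, outside the 50 bp window
        assert c.verdict == "pass"

    def test_bracket_sequence_length(self, rng):
        ref, matrix = designed_fixture(rng)
        for platform, flank in (("KASP", 50), ("Illumina", 60)):
            passing = [c for c in screen_matrix(matrix, ref, PARAMS, platform)
                       if c.verdict == "pass"]
            for c in passing:
                assert len(c.bracket_sequence) == 2 * flank + 5

    def test_reference_allele_listed_first(self, rng):
        ref, matrix = designed_fixture(rng)
        (passing,) = [c for c in screen_matrix(matrix, ref, PARAMS, "KASP")
                      if c.verdict == "pass"]
        ref_allele = ref[0].bases[passing.locus[1] - 1]
        assert passing.alleles[0] == ref_allele
        assert passing.alleles[1] != ref_allele


class TestWriters:
    def test_kasp_rows(self, rng, tmp_path):
        ref, matrix = designed_fixture(rng)
        candidates = screen_matrix(matrix, ref, PARAMS, "KASP")
        out = tmp_path / "kasp.tsv"
        n = write_kasp_input(candidates, out)
        lines = out.read_text().splitlines()
        assert n == 1 and len(lines) == 2
        fields = lines[1].split("\t")
        assert fields[0] == "chr1_500"
        left, rest = fields[1].split("[")
        alleles, right = rest.split("]")
        assert len(left) == len(right) == 50 and "/" in alleles

    def test_adt_columns(self, rng, tmp_path):
        ref, matrix = designed_fixture(rng)
        candidates = screen_matrix(matrix, ref, PARAMS, "Illumina")
        out = tmp_path / "adt.csv"
        n = write_adt_input(candidates, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "Locus_Name,Target_Type,Sequence,Chromosome,Coordinate"
        assert n == 1
        fields = lines[1].split(",")
        assert fields[1] == "SNP" and fields[3] == "chr1" and fields[4] == "500"

    def test_empty_candidate_set_header_only(self, tmp_path):
        for writer, name in ((write_kasp_input, "k.tsv"), (write_adt_input, "a.csv")):
            out = tmp_path / name
            assert writer([], out) == 0
            assert len(out.read_text().splitlines()) == 1


class TestGff3:
    def test_header_and_columns(self, rng, tmp_path):
        ref, matrix = designed_fixture(rng)
        out = tmp_path / "snps.gff3"
        n = write_gff3_snps(matrix, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert n == 5
        cols = lines[1].split("\t")
        assert cols[2] == "SNP" and cols[3] == cols[4] == "10"

    def test_parses_with_independent_parser(self, rng, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        ref, matrix = designed_fixture(rng)
        out = tmp_path / "snps.gff3"
        write_gff3_snps(matrix, out)
        db = gffutils.create_db(str(out), ":memory:")
        features = list(db.all_features())
        assert len(features) == 5
        assert {f.start for f in features} == {10, 200, 500, 800, 830}
        assert all(f.start == f.end for f in features)

    def test_empty_matrix_header_only(self, tmp_path):
        empty = SnpMatrix(loci=[], samples=["Reference"], alleles=[])
        out = tmp_path / "empty.gff3"
        assert write_gff3_snps(empty, out) == 0
        assert out.read_text() == "##gff-version 3\n"
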