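"""Genotyping-assay suitability filters and input-file writers.

A SNP is worth converting into a KASP or Illumina array assay only when a
probe can be designed around it, which imposes three criteria on its
flanking reference sequence:

  1. complete flanks — ``flank_len`` bases must exist on both sides;
  2. no ambiguous bases — flanks must be pure A/C/G/T (no N or IUPAC codes);
  3. no co-sited SNP — no other locus of the non-redundant matrix may fall
     inside the flank window.

Passing candidates are written as "left[X/Y]right" bracket-notation rows:
a KASP input TSV and an Illumina Assay Design Tool (ADT) preliminary CSV
(the two platforms require different flank lengths).  A GFF3 SNP track is
emitted for alignment viewers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

from .consensus import IUPAC_SETS, MISSING
from .markerstats import allele_frequencies
from .seqio import ReferenceSequence
from .snpcall import SnpMatrix

__all__ = [
    "AssayParams",
    "AssayCandidate",
    "extract_flanks",
    "screen_candidate",
    "screen_matrix",
    "write_kasp_input",
    "write_adt_input",
    "write_gff3_snps",
]

ACGT = set("ACGT")


@dataclass
class AssayParams:
    """Flank lengths per platform (KASP primers need ~50 bp of clean
    context, Illumina ADT submissions 60 bp); both configurable."""

    flank_len_kasp: int = 50
    flank_len_illumina: int = 60

    def __post_init__(self) -> None:
        if self.flank_len_kasp < 1 or self.flank_len_illumina < 1:
            raise ValueError("flank lengths must be >= 1")

    def flank_len(self, platform: str) -> int:
        if platform == "KASP":
            return self.flank_len_kasp
        if platform == "Illumina":
            return self.flank_len_illumina
        raise ValueError(f"unknown platform {platform!r}")


@dataclass
class AssayCandidate:
    locus: tuple[str, int]
    alleles: tuple[str, str]  # reference allele first
    left_flank: str
    right_flank: str
    platform: str
    fail_reasons: frozenset[str] = frozenset()

    @property
    def verdict(self) -> str:
        return "pass" if not self.fail_reasons else "fail"

    @property
    def bracket_sequence(self) -> str:
        x, y = self.alleles
        return f"{self.left_flank}[{x}/{y}]{self.right_flank}"


def extract_flanks(
    locus: tuple[str, int], reference: Sequence[ReferenceSequence], flank_len: int
) -> tuple[str, str] | None:
    """Reference bases [pos-flank_len, pos-1] and [pos+1, pos+flank_len]
    (1-based inclusive), or None when either window runs off the sequence."""
    ref_id, pos = locus
    bases = next((r.bases for r in reference if r.seq_id == ref_id), None)
    if bases is None:
        raise ValueError(f"unknown reference sequence {ref_id!r}")
    if pos - flank_len < 1 or pos + flank_len > len(bases):
        return None
    return bases[pos - flank_len - 1 : pos - 1], bases[pos : pos + flank_len]


def _snp_alleles(ref_allele: str, row: Sequence[str]) -> tuple[str, str]:
    """Assay allele pair: the reference allele first, then the most common
    alternative allele among the calls (ties alphabetical)."""
    freqs = allele_frequencies([c for c in row if c != MISSING] or [ref_allele])
    alts = sorted(
        ((f, b) for b, f in freqs.items() if b != ref_allele), key=lambda t: (-t[0], t[1])
    )
    alt = alts[0][1] if alts else ref_allele
    return ref_allele, alt


def screen_candidate(
    locus: tuple[str, int, str],
    row: Sequence[str],
    reference: Sequence[ReferenceSequence],
    all_loci: set[tuple[str, int]],
    params: AssayParams,
    platform: str,
) -> AssayCandidate:
    """Apply the three suitability criteria to one matrix locus."""
    ref_id, pos, ref_allele = locus
    flank_len = params.flank_len(platform)
    reasons: set[str] = set()
    flanks = extract_flanks((ref_id, pos), reference, flank_len)
    if flanks is None:
        left, right = "", ""
        reasons.add("incomplete_flank")
    else:
        left, right = flanks
        if any(ch not in ACGT for ch in left + right):
            reasons.add("ambiguous_base")
    for other_ref, other_pos in all_loci:
        if other_ref == ref_id and other_pos != pos and abs(other_pos - pos) <= flank_len:
            reasons.add("cosited_snp")
            break
    return AssayCandidate(
        locus=(ref_id, pos),
        alleles=_snp_alleles(ref_allele, row),
        left_flank=left,
        right_flank=right,
        platform=platform,
        fail_reasons=frozenset(reasons),
    )


def screen_matrix(
    matrix: SnpMatrix,
    reference: Sequence[ReferenceSequence],
    params: AssayParams,
    platform: str,
) -> list[AssayCandidate]:
    all_loci = matrix.locus_set()
    return [
        screen_candidate(locus, row, reference, all_loci, params, platform)
        for locus, row in zip(matrix.loci, matrix.alleles)
    ]


def write_kasp_input(candidates: Sequence[AssayCandidate], path: str | os.PathLike) -> int:
    """KASP order sheet: SNP id, bracket sequence, location (TSV).

    Only passing candidates are written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("SNP_id\tSequence\tref_id\tpos\n")
        for c in candidates:
            if c.fail_reasons:
                continue
            snp_id = f"{c.locus[0]}_{c.locus[1]}"
            fh.write(f"{snp_id}\t{c.bracket_sequence}\t{c.locus[0]}\t{c.locus[1]}\n")
            n += 1
    return n


def write_adt_input(candidates: Sequence[AssayCandidate], path: str | os.PathLike) -> int:
    """Illumina ADT preliminary submission file (CSV)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("Locus_Name,Target_Type,Sequence,Chromosome,Coordinate\n")
        for c in candidates:
            if c.fail_reasons:
                continue
            locus_name = f"{c.locus[0]}_{c.locus[1]}"
            fh.write(f"{locus_name},SNP,{c.bracket_sequence},{c.locus[0]},{c.locus[1]}\n")
            n += 1
    return n


def write_gff3_snps(
    matrix: SnpMatrix, path: str | os.PathLike, source: str = "snpmine"
) -> int:
    """One GFF3 SNP feature per matrix locus, with per-sample alleles in
    the attributes column; consumable by alignment viewers."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for (ref_id, pos, ref_allele), alleles in zip(matrix.loci, matrix.alleles):
            calls = ",".join(
                f"{s}:{a}" for s, a in zip(matrix.samples, alleles)
            )
            attrs = f"ID=snp_{ref_id}_{pos};ref_allele={ref_allele};alleles={calls}"
            fh.write(f"{ref_id}\t{source}\tSNP\t{pos}\t{pos}\t.\t.\t.\t{attrs}\n")
            n += 1
    return n
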