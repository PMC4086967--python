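"""Pairwise SNP detection and the non-redundant SNP genotype matrix.

SNPs are declared between every pair of samples and between each sample and
the reference; the union of all those positions forms a non-redundant locus
set reported as a genotype matrix (loci x samples, the reference as the
first pseudo-sample column, '-' for missing).

Two comparison modes are provided.  ``strict`` (default) declares a SNP
only where both samples carry an unambiguous major call and the calls
differ — the high-confidence set.  ``lenient`` also compares heterozygous
IUPAC calls, but suppresses nested pairs (e.g. A vs R, where {A} is a
subset of {A,G}) because they may share an allele.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consensus import MISSING, CallStatus, ConsensusCall, IUPAC_SETS
from .seqio import ReferenceSequence, write_tsv

__all__ = [
    "SnpMatrix",
    "pairwise_snps",
    "snps_vs_reference",
    "build_snp_matrix",
    "pairwise_count_table",
    "write_matrix_tsv",
    "write_pairwise_tsv",
    "write_called_allele_data",
    "REFERENCE_COLUMN",
]

REFERENCE_COLUMN = "Reference"

SampleCalls = Mapping[str, Mapping[int, ConsensusCall]]  # ref_id -> pos -> call


@dataclass
class SnpMatrix:
    """Non-redundant SNP genotype matrix.

    loci: ordered (ref_id, pos, ref_allele); samples: column order with the
    reference pseudo-sample first; alleles: per-locus list of call symbols
    aligned to ``samples`` ('-' for missing).
    """

    loci: list[tuple[str, int, str]]
    samples: list[str]
    alleles: list[list[str]]

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(
            [(r, p) for r, p, _ in self.loci], names=["ref_id", "pos"]
        )
        return pd.DataFrame(self.alleles, index=index, columns=self.samples)

    def locus_set(self) -> set[tuple[str, int]]:
        return {(r, p) for r, p, _ in self.loci}

    def row(self, ref_id: str, pos: int) -> list[str]:
        for (r, p, _), alleles in zip(self.loci, self.alleles):
            if (r, p) == (ref_id, pos):
                return alleles
        raise KeyError((ref_id, pos))


def _comparable(call: ConsensusCall, mode: str) -> bool:
    if call.status is CallStatus.MISSING:
        return False
    if mode == "strict":
        return call.status is CallStatus.MAJOR
    return True


def _differ(call_a: str, call_b: str, mode: str) -> bool:
    if call_a == call_b:
        return False
    if mode == "strict":
        return True
    set_a, set_b = IUPAC_SETS[call_a], IUPAC_SETS[call_b]
    # nested allele sets (A vs R) share an allele: not reported
    return not (set_a <= set_b or set_b <= set_a)


def pairwise_snps(
    calls_a: SampleCalls, calls_b: SampleCalls, mode: str = "strict"
) -> list[tuple[str, int]]:
    """Positions where two samples' consensus calls differ.

    Missing in either sample never reports; see module docstring for the
    strict/lenient semantics.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    out: list[tuple[str, int]] = []
    for ref_id in calls_a:
        if ref_id not in calls_b:
            continue
        b_positions = calls_b[ref_id]
        for pos, ca in calls_a[ref_id].items():
            cb = b_positions.get(pos)
            if cb is None:
                continue
            if not (_comparable(ca, mode) and _comparable(cb, mode)):
                continue
            if _differ(ca.call, cb.call, mode):
                out.append((ref_id, pos))
    return sorted(out)


def snps_vs_reference(
    calls: SampleCalls, reference: Sequence[ReferenceSequence], mode: str = "strict"
) -> list[tuple[str, int]]:
    """Positions where a sample's call differs from the reference base.

    Reference N positions are excluded.  In strict mode only major calls
    count; in lenient mode heterozygous calls not containing the reference
    allele also count.
    """
    ref_bases = {r.seq_id: r.bases for r in reference}
    out: list[tuple[str, int]] = []
    for ref_id, by_pos in calls.items():
        bases = ref_bases.get(ref_id)
        if bases is None:
            raise ValueError(f"calls reference unknown sequence {ref_id!r}")
        for pos, call in by_pos.items():
            ref_base = bases[pos - 1]
            if ref_base == "N":
                continue
            if not _comparable(call, mode):
                continue
            if _differ(call.call, ref_base, mode):
                out.append((ref_id, pos))
    return sorted(out)


def build_snp_matrix(
    all_calls: Mapping[str, SampleCalls],
    reference: Sequence[ReferenceSequence],
    mode: str = "strict",
) -> SnpMatrix:
    """Union of every pairwise and vs-reference SNP set, as a matrix."""
    ref_bases = {r.seq_id: r.bases for r in reference}
    samples = list(all_calls)
    loci: set[tuple[str, int]] = set()
    for name in samples:
        loci.update(snps_vs_reference(all_calls[name], reference, mode))
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            loci.update(pairwise_snps(all_calls[a], all_calls[b], mode))
    ordered = sorted(loci)
    rows: list[list[str]] = []
    loci_out: list[tuple[str, int, str]] = []
    for ref_id, pos in ordered:
        ref_allele = ref_bases[ref_id][pos - 1]
        row = [ref_allele]
        for name in samples:
            call = all_calls[name].get(ref_id, {}).get(pos)
            row.append(MISSING if call is None or call.status is CallStatus.MISSING else call.call)
        rows.append(row)
        loci_out.append((ref_id, pos, ref_allele))
    return SnpMatrix(loci=loci_out, samples=[REFERENCE_COLUMN] + samples, alleles=rows)


def pairwise_count_table(
    all_calls: Mapping[str, SampleCalls],
    reference: Sequence[ReferenceSequence],
    mode: str = "strict",
) -> pd.DataFrame:
    """Sample x sample SNP counts (symmetric, zero diagonal), with a
    reference row/column counting each sample's SNPs vs the reference."""
    samples = list(all_calls)
    names = [REFERENCE_COLUMN] + samples
    table = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in samples:
        n = len(snps_vs_reference(all_calls[name], reference, mode))
        table.loc[REFERENCE_COLUMN, name] = n
        table.loc[name, REFERENCE_COLUMN] = n
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            n = len(pairwise_snps(all_calls[a], all_calls[b], mode))
            table.loc[a, b] = n
            table.loc[b, a] = n
    return table


def write_matrix_tsv(matrix: SnpMatrix, path: str | os.PathLike) -> None:
    header = ["ref_id", "pos"] + matrix.samples
    rows = [
        [ref_id, pos] + alleles
        for (ref_id, pos, _), alleles in zip(matrix.loci, matrix.alleles)
    ]
    write_tsv(rows, path, header=header)


def write_pairwise_tsv(
    calls_a: SampleCalls,
    calls_b: SampleCalls,
    name_a: str,
    name_b: str,
    reference: Sequence[ReferenceSequence],
    path: str | os.PathLike,
    mode: str = "strict",
) -> int:
    """Per-pair SNP list with each sample's call, ratio and depth."""
    ref_bases = {r.seq_id: r.bases for r in reference}
    rows = []
    for ref_id, pos in pairwise_snps(calls_a, calls_b, mode):
        ca = calls_a[ref_id][pos]
        cb = calls_b[ref_id][pos]
        rows.append(
            [
                ref_id,
                pos,
                ref_bases[ref_id][pos - 1],
                ca.call,
                f"{ca.confidence_ratio:.3f}",
                ca.depth,
                cb.call,
                f"{cb.confidence_ratio:.3f}",
                cb.depth,
            ]
        )
    header = [
        "ref_id",
        "pos",
        "ref_allele",
        f"call_{name_a}",
        f"ratio_{name_a}",
        f"depth_{name_a}",
        f"call_{name_b}",
        f"ratio_{name_b}",
        f"depth_{name_b}",
    ]
    return write_tsv(rows, path, header=header)


def write_called_allele_data(
    matrix: SnpMatrix, stats: pd.DataFrame | None, path: str | os.PathLike
) -> None:
    """Spreadsheet-compatible flat file: the genotype matrix, one row per
    locus, joined with the marker statistics when available (TSV dialect)."""
    frame = matrix.to_frame().reset_index()
    frame.insert(2, "ref_allele", [a for _, _, a in matrix.loci])
    if stats is not None and not stats.empty:
        frame = frame.merge(stats, on=["ref_id", "pos"], how="left")
    frame.to_csv(os.fspath(path), sep="\t", index=False)
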