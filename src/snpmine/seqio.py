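"""Readers and writers for the standard formats the pipeline touches.

Dialect policy is strict on purpose: only Sanger (phred+33) FASTQ is
accepted, because every downstream quality rule (the Q20 base filter, the
Q20 pileup stack filter) is stated on the phred scale and silently rescaled
Illumina 1.3/1.5 input would corrupt them.  SAM files may lack a header
(converted Maq/SOAP alignments typically do); reference names and lengths
are then taken from the FASTA.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "Read",
    "ReferenceSequence",
    "AlignedRead",
    "Mate",
    "SamCounters",
    "VcfCounters",
    "FormatError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_sam",
    "read_vcf_candidates",
    "write_tsv",
]

PHRED_OFFSET = 33
MAX_SANGER_QUAL = 41  # highest quality Illumina 1.8+/Sanger emits in practice
MAX_QUAL = 93  # '~' under phred+33


class FormatError(ValueError):
    """Raised when an input file violates the accepted dialect."""


class Mate(Enum):
    NONE = "none"
    FIRST = "first"
    SECOND = "second"


@dataclass
class Read:
    """One sequencing read with per-base phred qualities."""

    read_id: str
    sequence: str
    quals: list[int]
    mate: Mate = Mate.NONE

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSequence:
    seq_id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignedRead:
    """A mapped SAM record reduced to the fields the pileup needs.

    ``pos`` is the 1-based leftmost reference coordinate, as printed in SAM.
    """

    read_id: str
    ref_id: str
    pos: int
    cigar: list[tuple[int, int]]  # pysam (op, length) tuples
    sequence: str
    quals: list[int]
    mapq: int
    flags: int


@dataclass
class SamCounters:
    records_in: int = 0
    used: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    malformed: int = 0

    @property
    def skipped(self) -> int:
        return self.unmapped + self.secondary + self.supplementary + self.malformed


@dataclass
class VcfCounters:
    records_in: int = 0
    used: int = 0
    non_snp: int = 0


def _decode_mate(read_id: str) -> tuple[str, Mate]:
    if read_id.endswith("/1"):
        return read_id, Mate.FIRST
    if read_id.endswith("/2"):
        return read_id, Mate.SECOND
    return read_id, Mate.NONE


def read_fastq(path: str | os.PathLike, strict_sanger: bool = True) -> Iterator[Read]:
    """Stream reads from a Sanger-encoded (phred+33) FASTQ file.

    Quality characters must lie in '!'..'~'.  With ``strict_sanger`` (the
    default) any quality decoding above 41 aborts with a "non-Sanger
    encoding suspected" error, so Illumina 1.3/1.5 files are rejected
    rather than silently rescaled.
    """
    path = os.fspath(path)
    try:
        for rec in SeqIO.parse(path, "fastq-sanger"):
            quals = list(rec.letter_annotations["phred_quality"])
            if strict_sanger and quals and max(quals) > MAX_SANGER_QUAL:
                raise FormatError(
                    f"{path}: read {rec.id} has phred quality {max(quals)} > "
                    f"{MAX_SANGER_QUAL}; non-Sanger encoding suspected "
                    "(Illumina 1.3/1.5 input is not accepted)"
                )
            read_id, mate = _decode_mate(rec.id)
            yield Read(read_id=read_id, sequence=str(rec.seq).upper(), quals=quals, mate=mate)
    except ValueError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a valid Sanger FASTQ file: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> int:
    """Write reads as 4-line phred+33 FASTQ records. Returns the count."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> list[ReferenceSequence]:
    """Load reference sequences; IDs must be unique, sequences non-empty."""
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        if not bases:
            raise FormatError(f"{path}: sequence {rec.id!r} is empty")
        records.append(ReferenceSequence(seq_id=rec.id, bases=bases))
    return records


def write_fasta(records: Iterable[ReferenceSequence], path: str | os.PathLike,
                width: int = 70) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")
            n += 1
    return n


def _sam_header(path: str, reference: Sequence[ReferenceSequence] | None) -> pysam.AlignmentHeader:
    """Build a pysam header from @SQ lines, or from the FASTA if absent."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                break
            if line.startswith("@SQ"):
                fields = dict(
                    f.split(":", 1) for f in line.rstrip("\n").split("\t")[1:] if ":" in f
                )
                if "SN" in fields and "LN" in fields:
                    names.append(fields["SN"])
                    lengths.append(int(fields["LN"]))
    if not names:
        if reference is None:
            raise FormatError(
                f"{path}: SAM file has no @SQ header lines and no reference "
                "FASTA was provided to supply sequence names/lengths"
            )
        names = [r.seq_id for r in reference]
        lengths = [len(r) for r in reference]
    return pysam.AlignmentHeader.from_references(names, lengths)


def read_sam(
    path: str | os.PathLike,
    reference: Sequence[ReferenceSequence] | None = None,
    counters: SamCounters | None = None,
    strict: bool = False,
) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from a SAM file.

    Unmapped (0x4), secondary (0x100) and supplementary (0x800) records are
    skipped and counted.  Records whose CIGAR does not consume exactly the
    query length are counted as malformed and skipped (``strict=True``
    aborts instead).  ``counters``, if given, is filled in place.
    """
    path = os.fspath(path)
    header = _sam_header(path, reference)
    c = counters if counters is not None else SamCounters()
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            c.records_in += 1
            try:
                seg = pysam.AlignedSegment.fromstring(line.rstrip("\n"), header)
            except ValueError as exc:
                if strict:
                    raise FormatError(f"{path}: malformed SAM record: {exc}") from exc
                c.malformed += 1
                continue
            if seg.is_unmapped:
                c.unmapped += 1
                continue
            if seg.is_secondary:
                c.secondary += 1
                continue
            if seg.is_supplementary:
                c.supplementary += 1
                continue
            if seg.query_sequence is None or seg.cigartuples is None:
                if strict:
                    raise FormatError(f"{path}: mapped record without SEQ/CIGAR")
                c.malformed += 1
                continue
            if seg.infer_query_length() != len(seg.query_sequence):
                if strict:
                    raise FormatError(
                        f"{path}: CIGAR consumes {seg.infer_query_length()} bases "
                        f"but sequence is {len(seg.query_sequence)} bp"
                    )
                c.malformed += 1
                continue
            c.used += 1
            quals = (
                list(seg.query_qualities)
                if seg.query_qualities is not None
                else [0] * len(seg.query_sequence)
            )
            yield AlignedRead(
                read_id=seg.query_name,
                ref_id=seg.reference_name,
                pos=seg.reference_start + 1,
                cigar=list(seg.cigartuples),
                sequence=seg.query_sequence.upper(),
                quals=quals,
                mapq=seg.mapping_quality,
                flags=seg.flag,
            )


def read_vcf_candidates(
    path: str | os.PathLike, counters: VcfCounters | None = None
) -> list[tuple[str, int, str, list[str]]]:
    """Read SNP candidate sites from a VCF; indel/MNP records are skipped.

    Returns (ref_id, pos 1-based, ref_allele, alt_alleles) tuples.
    """
    c = counters if counters is not None else VcfCounters()
    out: list[tuple[str, int, str, list[str]]] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            c.records_in += 1
            alts = [a for a in (rec.alts or ())]
            if len(rec.ref) != 1 or not alts or any(len(a) != 1 for a in alts):
                c.non_snp += 1
                continue
            c.used += 1
            out.append((rec.chrom, rec.pos, rec.ref.upper(), [a.upper() for a in alts]))
    return out


def write_tsv(
    rows: Iterable[Sequence], path: str | os.PathLike, header: Sequence[str] | None = None
) -> int:
    """Write rows as tab-separated text; fields must not contain tabs."""
    n = 0
    with open(path, "w") as fh:
        if header is not None:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fields = [str(x) for x in row]
            for f in fields:
                if "\t" in f or "\n" in f:
                    raise ValueError(f"field contains tab/newline: {f!r}")
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n
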