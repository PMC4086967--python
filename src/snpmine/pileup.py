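"""Per-position, quality-filtered base stacks from SAM alignments.

A position's "stack" is the multiset of aligned read bases covering it
whose base quality passes the phred filter (strictly greater than
``stack_qual_min``, Q20 by default).  Only CIGAR match columns (M/=/X)
contribute; soft clips and insertions consume query bases silently, and
deletions/skips leave the spanned reference positions uncounted — the
caller handles substitutions only.  N bases never enter the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import AlignedRead, ReferenceSequence

__all__ = ["PileupParams", "PositionStack", "SamplePileup", "build_pileup", "BASES"]

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

# pysam CIGAR operation codes
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S = 0, 1, 2, 3, 4
_CIGAR_H, _CIGAR_P, _CIGAR_EQ, _CIGAR_X = 5, 6, 7, 8
_CONSUMES_QUERY = {_CIGAR_M, _CIGAR_I, _CIGAR_S, _CIGAR_EQ, _CIGAR_X}
_CONSUMES_REF = {_CIGAR_M, _CIGAR_D, _CIGAR_N, _CIGAR_EQ, _CIGAR_X}
_MATCH_OPS = {_CIGAR_M, _CIGAR_EQ, _CIGAR_X}


@dataclass
class PileupParams:
    """stack_qual_min: bases with phred <= this are excluded (strict >20
    rule); mapq_min: records below are excluded entirely; min_depth is the
    consensus depth gate carried alongside for reporting."""

    stack_qual_min: int = 20
    mapq_min: int = 0
    min_depth: int = 3

    def __post_init__(self) -> None:
        if min(self.stack_qual_min, self.mapq_min, self.min_depth) < 0:
            raise ValueError("pileup parameters must be non-negative")


@dataclass
class PositionStack:
    """Quality-filtered base counts at one reference position."""

    ref_id: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, int]
    depth: int


class SamplePileup:
    """Base-count arrays for one sample over every reference sequence.

    ``counts[ref_id]`` is a (4, ref_len) int32 array in A,C,G,T order,
    0-based along the reference.  Iterating yields ``PositionStack`` for
    every covered position in coordinate order.
    """

    def __init__(self, reference: Sequence[ReferenceSequence]):
        self.refs = {r.seq_id: r.bases for r in reference}
        self.counts: dict[str, np.ndarray] = {
            r.seq_id: np.zeros((4, len(r)), dtype=np.int32) for r in reference
        }
        self.skipped_out_of_range = 0

    def counts_at(self, ref_id: str, pos: int) -> dict[str, int]:
        col = self.counts[ref_id][:, pos - 1]
        return {b: int(col[i]) for i, b in enumerate(BASES)}

    def stack_at(self, ref_id: str, pos: int) -> PositionStack:
        counts = self.counts_at(ref_id, pos)
        return PositionStack(
            ref_id=ref_id,
            pos=pos,
            ref_base=self.refs[ref_id][pos - 1],
            counts=counts,
            depth=sum(counts.values()),
        )

    def depth(self, ref_id: str) -> np.ndarray:
        return self.counts[ref_id].sum(axis=0)

    def __iter__(self) -> Iterator[PositionStack]:
        for ref_id in self.counts:
            covered = np.flatnonzero(self.depth(ref_id))
            for i in covered:
                yield self.stack_at(ref_id, int(i) + 1)

    def total_depth(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def _add_read(pile: SamplePileup, aln: AlignedRead, qual_min: int) -> bool:
    """Tally one alignment; returns False if it ran past the reference."""
    arr = pile.counts[aln.ref_id]
    ref_len = arr.shape[1]
    seq = np.frombuffer(aln.sequence.encode("ascii"), dtype=np.uint8)
    quals = np.asarray(aln.quals, dtype=np.int32)
    qpos = 0
    rpos = aln.pos - 1  # 0-based
    # dry-run bounds check so a bad record contributes nothing at all
    ref_span = sum(length for op, length in aln.cigar if op in _CONSUMES_REF)
    if rpos + ref_span > ref_len:
        return False
    for op, length in aln.cigar:
        if op in _MATCH_OPS:
            base_idx = _BASE_INDEX[seq[qpos : qpos + length]]
            ok = (base_idx >= 0) & (quals[qpos : qpos + length] > qual_min)
            positions = rpos + np.flatnonzero(ok)
            np.add.at(arr, (base_idx[ok].astype(np.intp), positions), 1)
            qpos += length
            rpos += length
        elif op in _CONSUMES_QUERY:
            qpos += length
        elif op in _CONSUMES_REF:
            rpos += length
        # H and P consume nothing
    return True


def build_pileup(
    alignments: Iterable[AlignedRead],
    reference: Sequence[ReferenceSequence],
    params: PileupParams | None = None,
) -> SamplePileup:
    """Tally quality-passing aligned bases per reference position.

    Records with mapq below ``mapq_min`` are excluded; an alignment naming
    an unknown reference is an error; one extending past the reference end
    is skipped and counted.
    """
    params = params or PileupParams()
    pile = SamplePileup(reference)
    for aln in alignments:
        if aln.ref_id not in pile.counts:
            raise ValueError(f"alignment {aln.read_id} references unknown sequence {aln.ref_id!r}")
        if aln.mapq < params.mapq_min:
            continue
        if not _add_read(pile, aln, params.stack_qual_min):
            pile.skipped_out_of_range += 1
    return pile
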