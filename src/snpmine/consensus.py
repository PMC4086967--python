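"""Coverage-based consensus calling (CbCC) and VCF-candidate confirmation.

At each covered position the major-allele frequency f = (top base count) /
(quality-filtered depth) decides the call: f >= f_major (0.66 by default,
i.e. 2/3 on a depth-3 stack) yields the major base; otherwise the two most
frequent bases are reported as an IUPAC ambiguity code, interpreted as a
heterozygous site.  Positions below ``min_depth`` are missing.  The f value
is reported as the call's confidence ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .pileup import BASES, PositionStack, SamplePileup

__all__ = [
    "ConsensusParams",
    "ConsensusCall",
    "CallStatus",
    "IUPAC_CODES",
    "IUPAC_SETS",
    "call_consensus",
    "call_sample",
    "confirm_vcf_candidates",
]

# two-base ambiguity codes, keys in alphabetical order
IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC_SETS: dict[str, frozenset[str]] = {
    **{b: frozenset(b) for b in BASES},
    **{code: bases for bases, code in IUPAC_CODES.items()},
}

MISSING = "-"


class CallStatus(Enum):
    MAJOR = "major"
    HETEROZYGOUS = "heterozygous"
    MISSING = "missing"


@dataclass
class ConsensusParams:
    """f_major: minimum major-allele frequency for an unambiguous call;
    min_depth: minimum quality-filtered depth for any call at all."""

    f_major: float = 0.66
    min_depth: int = 3

    def __post_init__(self) -> None:
        if not 0.5 < self.f_major <= 1.0:
            raise ValueError("f_major must be in (0.5, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class ConsensusCall:
    ref_id: str
    pos: int  # 1-based
    call: str  # A/C/G/T, two-base IUPAC code, or '-' when missing
    confidence_ratio: float
    depth: int
    status: CallStatus

    @property
    def allele_set(self) -> frozenset[str]:
        return IUPAC_SETS.get(self.call, frozenset())


def _ranked_bases(counts: Mapping[str, int]) -> list[str]:
    # count descending, then alphabetical — deterministic tie-break
    return sorted(BASES, key=lambda b: (-counts.get(b, 0), b))


def call_consensus(stack: PositionStack, params: ConsensusParams | None = None) -> ConsensusCall:
    """Call the consensus base for one sample at one position."""
    params = params or ConsensusParams()
    if stack.depth < params.min_depth:
        return ConsensusCall(
            ref_id=stack.ref_id,
            pos=stack.pos,
            call=MISSING,
            confidence_ratio=0.0,
            depth=stack.depth,
            status=CallStatus.MISSING,
        )
    ranked = _ranked_bases(stack.counts)
    top = ranked[0]
    f = stack.counts[top] / stack.depth
    if f >= params.f_major:
        return ConsensusCall(stack.ref_id, stack.pos, top, f, stack.depth, CallStatus.MAJOR)
    second = ranked[1]
    code = IUPAC_CODES[frozenset((top, second))]
    return ConsensusCall(stack.ref_id, stack.pos, code, f, stack.depth, CallStatus.HETEROZYGOUS)


def call_sample(
    pileup: SamplePileup, params: ConsensusParams | None = None
) -> dict[str, dict[int, ConsensusCall]]:
    """Consensus calls for every covered position, keyed ref_id -> pos.

    Positions whose quality-filtered depth is below ``min_depth`` are left
    out (they are missing, indistinguishable from uncovered positions).
    """
    params = params or ConsensusParams()
    calls: dict[str, dict[int, ConsensusCall]] = {}
    for ref_id, arr in pileup.counts.items():
        depth = arr.sum(axis=0)
        ref_calls: dict[int, ConsensusCall] = {}
        for i in np.flatnonzero(depth >= params.min_depth):
            stack = pileup.stack_at(ref_id, int(i) + 1)
            ref_calls[int(i) + 1] = call_consensus(stack, params)
        calls[ref_id] = ref_calls
    return calls


def confirm_vcf_candidates(
    candidates: Sequence[tuple[str, int, str, list[str]]],
    pileups_by_sample: Mapping[str, SamplePileup],
    params: ConsensusParams | None = None,
) -> tuple[dict[tuple[str, int], dict[str, ConsensusCall]], int]:
    """Confirm externally-called SNP candidates against the base stacks.

    Each candidate position gets a fresh consensus call per sample from its
    quality-filtered stack; a candidate is retained only if at least one
    sample's (non-missing) call differs from the reference allele.  Returns
    the confirmed calls keyed by (ref_id, pos) and the dropped count.
    """
    params = params or ConsensusParams()
    confirmed: dict[tuple[str, int], dict[str, ConsensusCall]] = {}
    dropped = 0
    for ref_id, pos, ref_allele, _alts in candidates:
        calls: dict[str, ConsensusCall] = {}
        any_variant = False
        for sample, pileup in pileups_by_sample.items():
            if ref_id not in pileup.counts or not 1 <= pos <= pileup.counts[ref_id].shape[1]:
                continue
            call = call_consensus(pileup.stack_at(ref_id, pos), params)
            calls[sample] = call
            if call.status is not CallStatus.MISSING and call.call != ref_allele:
                any_variant = True
        if any_variant:
            confirmed[(ref_id, pos)] = calls
        else:
            dropped += 1
    return confirmed, dropped
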