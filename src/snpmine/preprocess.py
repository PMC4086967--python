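"""Quality-based read filtering, dynamic end-trimming and pair synchronization.

The stage mirrors common practice for Illumina short reads: a read is
discarded when more than ``max_lowqual_fraction`` of its bases fall below
``base_qual_min`` (Q20 by default); the survivors define a per-position mean
quality profile from which one trim window per input file is derived and
applied uniformly, so every read of a file is cut to the same coordinates.
Paired-end files are then synchronized, discarding reads whose mate did not
survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import Mate, Read

__all__ = [
    "PreprocessParams",
    "QualityProfile",
    "TrimWindow",
    "PreprocessCounters",
    "filter_read",
    "build_quality_profile",
    "compute_trim_window",
    "trim_reads",
    "synchronize_pairs",
    "preprocess_report",
    "preprocess_file",
]


@dataclass
class PreprocessParams:
    """Thresholds of the filtering and trimming rules.

    base_qual_min
        A base counts as low-quality when its phred score is strictly below
        this (default 20, i.e. >1 % error probability).
    max_lowqual_fraction
        A read is discarded when the low-quality fraction strictly exceeds
        this (default 0.30).
    trim_offset
        The trim threshold T is the dataset mean phred minus this offset
        (default 3 phred units).
    jump_margin
        Scanning inward, trimming stops at the first position whose mean
        quality is at least T + jump_margin (default 1 phred unit) — the
        "sudden change" that marks the start of the good region.
    """

    base_qual_min: int = 20
    max_lowqual_fraction: float = 0.30
    trim_offset: float = 3.0
    jump_margin: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_lowqual_fraction <= 1.0:
            raise ValueError("max_lowqual_fraction must be in [0, 1]")
        if self.base_qual_min < 0:
            raise ValueError("base_qual_min must be >= 0")


@dataclass
class QualityProfile:
    """Positional mean phred scores of the filter-surviving reads."""

    per_position_mean: list[float]
    dataset_mean: float
    n_reads: int


@dataclass
class TrimWindow:
    """1-based inclusive coordinates of the retained read region."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid trim window ({self.start}, {self.end})")


@dataclass
class PreprocessCounters:
    raw: int = 0
    kept: int = 0
    filter_discarded: int = 0
    trim_discarded: int = 0
    orphaned: int = 0


def filter_read(read: Read, params: PreprocessParams) -> bool:
    """True to keep the read, False to discard it.

    Discards iff the fraction of bases with phred < ``base_qual_min``
    strictly exceeds ``max_lowqual_fraction``.
    """
    if len(read) == 0:
        return False
    n_low = sum(1 for q in read.quals if q < params.base_qual_min)
    return not (n_low / len(read) > params.max_lowqual_fraction)


def build_quality_profile(reads: Iterable[Read]) -> QualityProfile:
    """Per-position and whole-dataset mean phred over filter-surviving reads.

    Positions beyond a shorter read's length are averaged over the reads
    that actually cover them.
    """
    sums = np.zeros(0, dtype=np.float64)
    covers = np.zeros(0, dtype=np.int64)
    total = 0.0
    n_bases = 0
    n_reads = 0
    for read in reads:
        q = np.asarray(read.quals, dtype=np.float64)
        if q.size > sums.size:
            sums = np.concatenate([sums, np.zeros(q.size - sums.size)])
            covers = np.concatenate([covers, np.zeros(q.size - covers.size, dtype=np.int64)])
        sums[: q.size] += q
        covers[: q.size] += 1
        total += q.sum()
        n_bases += q.size
        n_reads += 1
    if n_reads == 0 or n_bases == 0:
        raise ValueError("no reads survive filtering; cannot build quality profile")
    return QualityProfile(
        per_position_mean=list(sums / covers),
        dataset_mean=total / n_bases,
        n_reads=n_reads,
    )


def compute_trim_window(profile: QualityProfile, params: PreprocessParams) -> TrimWindow:
    """Locate the retained region from the positional quality profile.

    With T = dataset_mean − trim_offset, the scan moves inward from each
    end and trims until the first position whose mean phred is at least
    T + jump_margin; that position becomes the window boundary.  A
    uniformly high profile therefore yields the identity window.
    """
    means = profile.per_position_mean
    if not means:
        raise ValueError("empty quality profile")
    cut = profile.dataset_mean - params.trim_offset + params.jump_margin
    start = None
    for i, m in enumerate(means):
        if m >= cut:
            start = i + 1
            break
    if start is None:
        raise ValueError("dataset quality below trim threshold: entire read trimmed")
    end = None
    for i in range(len(means) - 1, -1, -1):
        if means[i] >= cut:
            end = i + 1
            break
    assert end is not None and end >= start
    return TrimWindow(start=start, end=end)


def trim_reads(
    reads: Iterable[Read], window: TrimWindow, counters: PreprocessCounters | None = None
) -> Iterator[Read]:
    """Cut every read to the window's 1-based [start, end], clipped to its
    length; reads shorter than ``start`` are discarded and counted."""
    for read in reads:
        if len(read) < window.start:
            if counters is not None:
                counters.trim_discarded += 1
            continue
        end = min(window.end, len(read))
        yield Read(
            read_id=read.read_id,
            sequence=read.sequence[window.start - 1 : end],
            quals=read.quals[window.start - 1 : end],
            mate=read.mate,
        )


def pair_key(read_id: str) -> str:
    """Mate-pair key: the read id minus a trailing /1 or /2."""
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def synchronize_pairs(
    reads1: Sequence[Read], reads2: Sequence[Read]
) -> tuple[list[Read], list[Read], int]:
    """Keep only reads whose mate survives in the other file.

    Returns the two order-aligned paired lists and the orphan count.
    Duplicate read ids within one file are an error.
    """
    by_key: dict[str, Read] = {}
    for r in reads2:
        k = pair_key(r.read_id)
        if k in by_key:
            raise ValueError(f"duplicate read id {r.read_id!r} in second file")
        by_key[k] = r
    seen1: set[str] = set()
    out1: list[Read] = []
    out2: list[Read] = []
    for r in reads1:
        k = pair_key(r.read_id)
        if k in seen1:
            raise ValueError(f"duplicate read id {r.read_id!r} in first file")
        seen1.add(k)
        mate = by_key.pop(k, None)
        if mate is not None:
            out1.append(r)
            out2.append(mate)
    orphans = (len(reads1) - len(out1)) + len(by_key)
    return out1, out2, orphans


def preprocess_report(
    counters: PreprocessCounters,
    profile: QualityProfile | None,
    windows: dict[str, TrimWindow],
) -> dict:
    """Summary record: raw/kept counts, retention, trim coordinates."""
    retained_pct = 100.0 * counters.kept / counters.raw if counters.raw else 0.0
    return {
        "raw_reads": counters.raw,
        "kept_reads": counters.kept,
        "filter_discarded": counters.filter_discarded,
        "trim_discarded": counters.trim_discarded,
        "orphaned": counters.orphaned,
        "retained_pct": round(retained_pct, 2),
        "dataset_mean_phred": round(profile.dataset_mean, 3) if profile else None,
        "trim_windows": {name: f"keep {w.start}-{w.end}" for name, w in windows.items()},
    }


def preprocess_file(
    reads: Iterable[Read], params: PreprocessParams
) -> tuple[list[Read], TrimWindow, QualityProfile, PreprocessCounters]:
    """Filter, profile and trim one FASTQ file's reads (single window)."""
    counters = PreprocessCounters()
    kept: list[Read] = []
    for read in reads:
        counters.raw += 1
        if filter_read(read, params):
            kept.append(read)
        else:
            counters.filter_discarded += 1
    profile = build_quality_profile(kept)
    window = compute_trim_window(profile, params)
    trimmed = list(trim_reads(kept, window, counters))
    counters.kept = len(trimmed)
    return trimmed, window, profile, counters
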