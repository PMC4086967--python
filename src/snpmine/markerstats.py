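"""Marker informativeness statistics over the SNP genotype matrix.

Allele frequencies are obtained by copy counting: an unambiguous call
contributes two copies of its base (a diploid homozygote), a two-base
IUPAC heterozygote one copy of each constituent, and missing calls
nothing.  From the frequency vector p the module reports

    minor allele frequency   MAF = second-largest p_i
    expected heterozygosity  He  = 1 - sum p_i^2
    polymorphism information content (Botstein et al. form)
                             PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

PIC <= He always; both are 0 for a monomorphic locus and, for a biallelic
locus, peak at p = 0.5 (He 0.5, PIC 0.375).  High-PIC markers segregate
informatively in a germplasm panel and are the ones worth genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .consensus import MISSING, IUPAC_SETS
from .snpcall import SnpMatrix

__all__ = [
    "MarkerStats",
    "allele_frequencies",
    "compute_pic",
    "compute_heterozygosity",
    "compute_maf",
    "marker_stats",
    "marker_stats_table",
]


@dataclass
class MarkerStats:
    locus: tuple[str, int]
    allele_freqs: dict[str, float]
    maf: float
    heterozygosity: float
    pic: float
    n_typed: int


def allele_frequencies(calls: Sequence[str]) -> dict[str, float]:
    """Allele proportions from a matrix row of call symbols.

    Homozygous calls count 2 copies, IUPAC heterozygotes 1 copy per
    constituent base, '-' nothing.  An all-missing row is an error.
    """
    copies: dict[str, int] = {}
    for symbol in calls:
        if symbol == MISSING:
            continue
        alleles = IUPAC_SETS.get(symbol)
        if alleles is None:
            raise ValueError(f"unrecognized call symbol {symbol!r}")
        if len(alleles) == 1:
            (base,) = alleles
            copies[base] = copies.get(base, 0) + 2
        else:
            for base in alleles:
                copies[base] = copies.get(base, 0) + 1
    total = sum(copies.values())
    if total == 0:
        raise ValueError("all calls missing: no alleles to count")
    return {base: n / total for base, n in sorted(copies.items())}


def compute_heterozygosity(freqs: Mapping[str, float]) -> float:
    """Expected heterozygosity He = 1 - sum p_i^2."""
    return 1.0 - sum(p * p for p in freqs.values())


def compute_pic(freqs: Mapping[str, float]) -> float:
    """Polymorphism information content, full Botstein form."""
    p = list(freqs.values())
    sum_sq = sum(x * x for x in p)
    cross = sum(
        2.0 * p[i] * p[i] * p[j] * p[j] for i in range(len(p)) for j in range(i + 1, len(p))
    )
    return 1.0 - sum_sq - cross


def compute_maf(freqs: Mapping[str, float]) -> float:
    """Minor allele frequency: the second-largest allele proportion
    (0 for a monomorphic locus)."""
    ranked = sorted(freqs.values(), reverse=True)
    return ranked[1] if len(ranked) > 1 else 0.0


def marker_stats(
    locus: tuple[str, int], calls: Sequence[str]
) -> MarkerStats:
    freqs = allele_frequencies(calls)
    return MarkerStats(
        locus=locus,
        allele_freqs=freqs,
        maf=compute_maf(freqs),
        heterozygosity=compute_heterozygosity(freqs),
        pic=compute_pic(freqs),
        n_typed=sum(1 for c in calls if c != MISSING),
    )


def marker_stats_table(matrix: SnpMatrix, include_reference: bool = True) -> pd.DataFrame:
    """Per-locus statistics over the whole matrix.

    ``include_reference=False`` drops the reference pseudo-sample column
    from the frequency panel.  Loci left all-missing by the exclusion are
    reported with NaN statistics.
    """
    start = 0 if include_reference else 1
    rows = []
    for (ref_id, pos, ref_allele), alleles in zip(matrix.loci, matrix.alleles):
        panel = alleles[start:]
        try:
            st = marker_stats((ref_id, pos), panel)
        except ValueError:
            rows.append([ref_id, pos, ref_allele, "", None, None, None, 0])
            continue
        freq_str = ",".join(f"{b}:{f:.4f}" for b, f in st.allele_freqs.items())
        rows.append(
            [ref_id, pos, ref_allele, freq_str,
             round(st.maf, 6), round(st.heterozygosity, 6), round(st.pic, 6), st.n_typed]
        )
    return pd.DataFrame(
        rows,
        columns=["ref_id", "pos", "ref_allele", "allele_freqs", "maf", "he", "pic", "n_typed"],
    )
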