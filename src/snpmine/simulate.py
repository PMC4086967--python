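"""Deterministic synthetic datasets with planted SNPs and a truth table.

The generator emulates the study design the pipeline targets: a reference
sequence, several samples each carrying planted homozygous or heterozygous
substitution SNPs at known positions, Illumina-like short reads of uniform
length with configurable coverage, per-base quality profile (optionally
degraded towards the 3' end) and substitution error rate — and, because
alignment itself is delegated to external tools, the matching *error-free
placement* SAM records (full-match CIGAR at the true position).  Every
stage of the pipeline is therefore testable against the returned truth
table without downloads or an aligner.

All randomness flows from the single ``seed`` in ``SimulationConfig``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqio import AlignedRead, Mate, Read, ReferenceSequence, write_fasta, write_fastq, write_tsv

__all__ = [
    "SimulationConfig",
    "TruthLocus",
    "TruthTable",
    "SimulatedDataset",
    "simulate_reference",
    "plant_variants",
    "simulate_reads_and_sam",
    "simulate_dataset",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
HET_CODES = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    coverage is the expected fold-coverage per sample; error_rate the
    per-base substitution probability; base_quality the mean phred of a
    healthy cycle, with the last ``decay_span`` cycles declining linearly
    to ``end_quality`` (decay_span 0 disables degradation); qual_jitter is
    the s.d. of integer noise around the positional mean.  end_margin
    (default: read_length) keeps planted SNPs away from sequence ends so
    they are evenly covered.
    """

    seed: int = 0
    ref_length: int = 10_000
    n_samples: int = 2
    n_snps: int = 50
    het_fraction: float = 0.0
    alt_prob: float = 0.5
    coverage: float = 30.0
    read_length: int = 100
    paired: bool = False
    insert_gap: int = 50
    error_rate: float = 0.0
    base_quality: int = 38
    end_quality: int = 20
    decay_span: int = 0
    qual_jitter: float = 0.0
    end_margin: int | None = None
    ref_id: str = "ref1"

    def __post_init__(self) -> None:
        if self.n_snps >= self.ref_length:
            raise ValueError("n_snps must be smaller than ref_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must be in [0, 1]")

    @property
    def margin(self) -> int:
        return self.read_length if self.end_margin is None else self.end_margin


@dataclass
class TruthLocus:
    ref_id: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, str]  # sample -> hom_ref | hom_alt | het

    def expected_call(self, sample: str) -> str:
        g = self.genotypes[sample]
        if g == "hom_ref":
            return self.ref_allele
        if g == "hom_alt":
            return self.alt_allele
        return HET_CODES[frozenset((self.ref_allele, self.alt_allele))]


@dataclass
class TruthTable:
    loci: list[TruthLocus]
    samples: list[str]

    def pairwise_positions(self, a: str, b: str, homozygous_only: bool = True) -> set[tuple[str, int]]:
        """Positions where the planted genotypes of two samples differ."""
        out = set()
        for locus in self.loci:
            ga, gb = locus.genotypes[a], locus.genotypes[b]
            if homozygous_only and ("het" in (ga, gb)):
                continue
            if ga != gb:
                out.add((locus.ref_id, locus.pos))
        return out

    def vs_reference_positions(self, sample: str) -> set[tuple[str, int]]:
        return {
            (l.ref_id, l.pos)
            for l in self.loci
            if l.genotypes[sample] == "hom_alt"
        }

    def write_tsv(self, path: str | os.PathLike) -> None:
        header = ["ref_id", "pos", "ref_allele", "alt_allele"] + list(self.samples)
        rows = [
            [l.ref_id, l.pos, l.ref_allele, l.alt_allele] + [l.genotypes[s] for s in self.samples]
            for l in self.loci
        ]
        write_tsv(rows, path, header=header)


def simulate_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> ReferenceSequence:
    """Uniform random A/C/G/T sequence, reproducible from the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bases = _BASES[rng.integers(0, 4, size=config.ref_length)]
    return ReferenceSequence(seq_id=config.ref_id, bases=bases.tobytes().decode("ascii"))


def plant_variants(
    reference: ReferenceSequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genotypes: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, tuple[str, str]], TruthTable]:
    """Plant n_snps biallelic substitutions and build sample haplotypes.

    Positions are drawn without replacement at least ``margin`` bases from
    either end.  Each sample is independently assigned hom_ref / hom_alt /
    het per locus (het with probability het_fraction, otherwise hom_alt
    with probability alt_prob) unless an explicit ``genotypes`` mapping
    (sample -> one genotype string per locus, in position order) is given.
    Heterozygous loci put the alternative allele on one of the sample's two
    haplotypes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    lo, hi = config.margin + 1, len(reference) - config.margin  # 1-based bounds
    if hi < lo or hi - lo + 1 < config.n_snps:
        raise ValueError(
            f"cannot place {config.n_snps} SNPs in [{lo}, {hi}] of a "
            f"{len(reference)} bp reference with margin {config.margin}"
        )
    positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=config.n_snps, replace=False))
    samples = [f"sample{i + 1}" for i in range(config.n_samples)]
    loci: list[TruthLocus] = []
    haplotype_arrays = {
        s: (
            np.frombuffer(reference.bases.encode(), dtype=np.uint8).copy(),
            np.frombuffer(reference.bases.encode(), dtype=np.uint8).copy(),
        )
        for s in samples
    }
    for idx, pos in enumerate(int(p) for p in positions):
        ref_allele = reference.bases[pos - 1]
        alt_allele = rng.choice([b for b in "ACGT" if b != ref_allele])
        locus_genotypes: dict[str, str] = {}
        for s in samples:
            if genotypes is not None:
                g = genotypes[s][idx]
            elif rng.random() < config.het_fraction:
                g = "het"
            else:
                g = "hom_alt" if rng.random() < config.alt_prob else "hom_ref"
            locus_genotypes[s] = g
            hap1, hap2 = haplotype_arrays[s]
            if g == "hom_alt":
                hap1[pos - 1] = ord(alt_allele)
                hap2[pos - 1] = ord(alt_allele)
            elif g == "het":
                (hap1 if rng.random() < 0.5 else hap2)[pos - 1] = ord(alt_allele)
        loci.append(TruthLocus(reference.seq_id, pos, ref_allele, alt_allele, locus_genotypes))
    haplotypes = {
        s: (h1.tobytes().decode("ascii"), h2.tobytes().decode("ascii"))
        for s, (h1, h2) in haplotype_arrays.items()
    }
    return haplotypes, TruthTable(loci=loci, samples=samples)


def _quality_means(config: SimulationConfig) -> np.ndarray:
    means = np.full(config.read_length, float(config.base_quality))
    span = min(config.decay_span, config.read_length)
    if span > 0:
        means[-span:] = np.linspace(config.base_quality, config.end_quality, span)
    return means


def simulate_reads_and_sam(
    haplotypes: Mapping[str, tuple[str, str]],
    config: SimulationConfig,
    ref_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[list[Read], list[AlignedRead], int]]:
    """Draw reads uniformly along each sample's haplotypes.

    Returns, per sample, the reads, their true-placement alignments
    (full-match CIGAR) and the number of injected substitution errors.
    Paired mode emits mate pairs ``<id>/1``, ``<id>/2`` from opposite ends
    of a fragment of 2*read_length + insert_gap bases.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    ref_id = ref_id or config.ref_id
    L = config.read_length
    qual_means = _quality_means(config)
    out: dict[str, tuple[list[Read], list[AlignedRead], int]] = {}
    for sample, haps in haplotypes.items():
        hap_arrays = [np.frombuffer(h.encode(), dtype=np.uint8) for h in haps]
        ref_len = hap_arrays[0].size
        if L > ref_len:
            raise ValueError("read_length exceeds reference length")
        frag = 2 * L + config.insert_gap if config.paired else L
        if frag > ref_len:
            raise ValueError("fragment length exceeds reference length")
        n_frags = int(round(config.coverage * ref_len / (2 * L if config.paired else L)))
        reads: list[Read] = []
        alignments: list[AlignedRead] = []
        n_errors = 0
        starts = rng.integers(0, ref_len - frag + 1, size=n_frags)
        hap_choice = rng.integers(0, 2, size=n_frags)
        for i in range(n_frags):
            hap = hap_arrays[hap_choice[i]]
            start = int(starts[i])
            if config.paired:
                segments = [(start, Mate.FIRST, 0x1 | 0x2 | 0x40),
                            (start + L + config.insert_gap, Mate.SECOND, 0x1 | 0x2 | 0x80)]
            else:
                segments = [(start, Mate.NONE, 0)]
            for seg_start, mate, flags in segments:
                seq = hap[seg_start : seg_start + L].copy()
                if config.error_rate > 0:
                    err_mask = rng.random(L) < config.error_rate
                    for j in np.flatnonzero(err_mask):
                        choices = _BASES[_BASES != seq[j]]
                        seq[j] = rng.choice(choices)
                    n_errors += int(err_mask.sum())
                quals = qual_means.copy()
                if config.qual_jitter > 0:
                    quals = quals + rng.normal(0.0, config.qual_jitter, L)
                qlist = [int(q) for q in np.clip(np.rint(quals), 2, 41)]
                suffix = {Mate.FIRST: "/1", Mate.SECOND: "/2", Mate.NONE: ""}[mate]
                read_id = f"{sample}_r{i + 1}{suffix}"
                sequence = seq.tobytes().decode("ascii")
                reads.append(Read(read_id=read_id, sequence=sequence, quals=qlist, mate=mate))
                alignments.append(
                    AlignedRead(
                        read_id=read_id,
                        ref_id=ref_id,
                        pos=seg_start + 1,
                        cigar=[(0, L)],
                        sequence=sequence,
                        quals=qlist,
                        mapq=60,
                        flags=flags,
                    )
                )
        out[sample] = (reads, alignments, n_errors)
    return out


def write_sam(
    alignments: Sequence[AlignedRead],
    reference: ReferenceSequence,
    path: str | os.PathLike,
    with_header: bool = True,
) -> None:
    """Serialize alignments as SAM text (optionally headerless, as
    converted Maq/SOAP output would be)."""
    def cigar_str(cigar: list[tuple[int, int]]) -> str:
        ops = "MIDNSHP=X"
        return "".join(f"{length}{ops[op]}" for op, length in cigar)

    with open(path, "w") as fh:
        if with_header:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{reference.seq_id}\tLN:{len(reference)}\n")
        for a in alignments:
            qual = "".join(chr(q + 33) for q in a.quals)
            fh.write(
                f"{a.read_id}\t{a.flags}\t{a.ref_id}\t{a.pos}\t{a.mapq}\t"
                f"{cigar_str(a.cigar)}\t*\t0\t0\t{a.sequence}\t{qual}\n"
            )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: ReferenceSequence
    haplotypes: dict[str, tuple[str, str]]
    truth: TruthTable
    reads: dict[str, list[Read]]
    alignments: dict[str, list[AlignedRead]]
    n_errors: dict[str, int]

    def write(self, outdir: str | os.PathLike, sam_header: bool = True) -> dict[str, str]:
        """Write FASTA/FASTQ/SAM/truth-TSV under outdir; returns paths."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {"reference": os.path.join(outdir, "reference.fasta")}
        write_fasta([self.reference], paths["reference"])
        for sample in self.truth.samples:
            fq = os.path.join(outdir, f"{sample}.fastq")
            sam = os.path.join(outdir, f"{sample}.sam")
            write_fastq(self.reads[sample], fq)
            write_sam(self.alignments[sample], self.reference, sam, with_header=sam_header)
            paths[f"{sample}.fastq"] = fq
            paths[f"{sample}.sam"] = sam
        paths["truth"] = os.path.join(outdir, "truth.tsv")
        self.truth.write_tsv(paths["truth"])
        return paths


def simulate_dataset(
    config: SimulationConfig, genotypes: Mapping[str, Sequence[str]] | None = None
) -> SimulatedDataset:
    """One-call generator: reference, planted variants, reads, alignments."""
    root = np.random.default_rng(config.seed)
    ref_rng, var_rng, read_rng = root.spawn(3)
    reference = simulate_reference(config, ref_rng)
    haplotypes, truth = plant_variants(reference, config, var_rng, genotypes=genotypes)
    per_sample = simulate_reads_and_sam(haplotypes, config, reference.seq_id, read_rng)
    return SimulatedDataset(
        config=config,
        reference=reference,
        haplotypes=haplotypes,
        truth=truth,
        reads={s: r for s, (r, _, _) in per_sample.items()},
        alignments={s: a for s, (_, a, _) in per_sample.items()},
        n_errors={s: e for s, (_, _, e) in per_sample.items()},
    )
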