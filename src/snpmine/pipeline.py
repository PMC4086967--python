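"""Staged pipeline runner: import -> preprocess -> call -> matrix -> stats -> assay.

Each stage is a file-in/file-out function; ``run_pipeline`` chains them on
one output directory, so a full run and the equivalent sequence of CLI
subcommands produce identical files.  Stage completion is recorded in
``stages.log`` inside the output directory; on a stage failure the log
shows the last completed stage, making a rerun resumable by hand.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from . import assaydesign, markerstats, preprocess, snpcall
from .consensus import CallStatus, ConsensusCall, ConsensusParams, call_sample
from .pileup import PileupParams, build_pileup
from .seqio import (
    ReferenceSequence,
    SamCounters,
    read_fasta,
    read_fastq,
    read_sam,
    read_vcf_candidates,
    write_fastq,
    write_tsv,
)

__all__ = [
    "SampleSpec",
    "RunConfig",
    "StageError",
    "run_pipeline",
    "stage_preprocess",
    "stage_call",
    "stage_matrix",
    "stage_stats",
    "stage_assay",
    "write_consensus_tsv",
    "read_consensus_tsv",
    "read_matrix_tsv",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class SampleSpec:
    name: str
    sam: str
    fastq: list[str] = field(default_factory=list)
    vcf: str | None = None


@dataclass
class RunConfig:
    """Declarative run description; defaults mirror the pipeline's stated
    thresholds (Q20 base filter, 30 % low-quality cap, trim offset −3 /
    jump +1, F_major 0.66)."""

    reference: str
    samples: list[SampleSpec]
    outdir: str
    run_preprocess: bool = False
    snp_mode: str = "cbcc"  # cbcc | vcf
    comparison_mode: str = "strict"  # strict | lenient
    include_reference_in_stats: bool = True
    min_pic: float | None = None
    preprocess_params: preprocess.PreprocessParams = field(
        default_factory=preprocess.PreprocessParams
    )
    pileup_params: PileupParams = field(default_factory=PileupParams)
    consensus_params: ConsensusParams = field(default_factory=ConsensusParams)
    assay_params: assaydesign.AssayParams = field(default_factory=assaydesign.AssayParams)

    def __post_init__(self) -> None:
        if self.snp_mode not in ("cbcc", "vcf"):
            raise ValueError(f"unknown snp_mode {self.snp_mode!r}")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        params = {
            "preprocess_params": preprocess.PreprocessParams,
            "pileup_params": PileupParams,
            "consensus_params": ConsensusParams,
            "assay_params": assaydesign.AssayParams,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in params:
                kwargs[key] = params[key](**val)
            else:
                kwargs[key] = val
        return cls(samples=samples, **kwargs)


# ---------------------------------------------------------------- stages

def stage_preprocess(
    fastq_paths: Sequence[str],
    params: preprocess.PreprocessParams,
    outdir: str,
    sample: str,
) -> dict:
    """Filter/trim one sample's FASTQ file(s); paired inputs (two files)
    are synchronized after trimming.  Writes the high-quality FASTQ(s) and
    returns the report record."""
    os.makedirs(outdir, exist_ok=True)
    if len(fastq_paths) not in (1, 2):
        raise ValueError("expected one (SE) or two (PE) FASTQ files per sample")
    results = [preprocess.preprocess_file(read_fastq(p), params) for p in fastq_paths]
    windows = {
        os.path.basename(p): window for p, (_, window, _, _) in zip(fastq_paths, results)
    }
    counters = preprocess.PreprocessCounters()
    for _, _, _, c in results:
        counters.raw += c.raw
        counters.filter_discarded += c.filter_discarded
        counters.trim_discarded += c.trim_discarded
    if len(results) == 2:
        paired1, paired2, orphans = preprocess.synchronize_pairs(results[0][0], results[1][0])
        counters.orphaned = orphans
        outputs = [paired1, paired2]
    else:
        outputs = [results[0][0]]
    counters.kept = sum(len(o) for o in outputs)
    out_paths = []
    for i, (path, reads) in enumerate(zip(fastq_paths, outputs), start=1):
        suffix = f"_{i}" if len(outputs) == 2 else ""
        out = os.path.join(outdir, f"{sample}{suffix}.hq.fastq")
        write_fastq(reads, out)
        out_paths.append(out)
    profile = results[0][2]
    report = preprocess.preprocess_report(counters, profile, windows)
    report["sample"] = sample
    report["outputs"] = out_paths
    return report


def write_consensus_tsv(
    calls: Mapping[str, Mapping[int, ConsensusCall]],
    reference: Sequence[ReferenceSequence],
    path: str | os.PathLike,
) -> int:
    ref_bases = {r.seq_id: r.bases for r in reference}
    rows = []
    for ref_id in sorted(calls):
        for pos in sorted(calls[ref_id]):
            c = calls[ref_id][pos]
            rows.append(
                [ref_id, pos, ref_bases[ref_id][pos - 1], c.call,
                 f"{c.confidence_ratio:.6f}", c.depth, c.status.value]
            )
    return write_tsv(
        rows, path,
        header=["ref_id", "pos", "ref_base", "call", "confidence_ratio", "depth", "status"],
    )


def read_consensus_tsv(path: str | os.PathLike) -> dict[str, dict[int, ConsensusCall]]:
    calls: dict[str, dict[int, ConsensusCall]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            ref_id, pos, _ref, call, ratio, depth, status = line.rstrip("\n").split("\t")
            calls.setdefault(ref_id, {})[int(pos)] = ConsensusCall(
                ref_id=ref_id,
                pos=int(pos),
                call=call,
                confidence_ratio=float(ratio),
                depth=int(depth),
                status=CallStatus(status),
            )
    return calls


def stage_call(
    sam_path: str,
    reference: Sequence[ReferenceSequence],
    pileup_params: PileupParams,
    consensus_params: ConsensusParams,
    out_tsv: str,
    candidate_positions: set[tuple[str, int]] | None = None,
) -> dict:
    """Pileup + consensus for one sample's SAM; writes the consensus dump.

    With ``candidate_positions`` (VCF-candidate mode) only those positions
    are called and dumped — the cross-sample confirmation happens at the
    matrix stage, where positions at which every sample matches the
    reference drop out.
    """
    counters = SamCounters()
    pile = build_pileup(read_sam(sam_path, reference, counters), reference, pileup_params)
    calls = call_sample(pile, consensus_params)
    if candidate_positions is not None:
        calls = {
            ref_id: {
                pos: c for pos, c in by_pos.items() if (ref_id, pos) in candidate_positions
            }
            for ref_id, by_pos in calls.items()
        }
    n = write_consensus_tsv(calls, reference, out_tsv)
    return {
        "sam": sam_path,
        "records_in": counters.records_in,
        "records_used": counters.used,
        "unmapped": counters.unmapped,
        "secondary": counters.secondary,
        "supplementary": counters.supplementary,
        "malformed": counters.malformed,
        "called_positions": n,
        "out": out_tsv,
    }


def stage_matrix(
    consensus_tsvs: Mapping[str, str],
    reference: Sequence[ReferenceSequence],
    mode: str,
    outdir: str,
) -> dict:
    """Pairwise SNP lists, the non-redundant matrix and the count table."""
    os.makedirs(outdir, exist_ok=True)
    all_calls = {name: read_consensus_tsv(path) for name, path in consensus_tsvs.items()}
    matrix = snpcall.build_snp_matrix(all_calls, reference, mode)
    matrix_path = os.path.join(outdir, "snp_matrix.tsv")
    snpcall.write_matrix_tsv(matrix, matrix_path)
    names = list(all_calls)
    pair_files = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = os.path.join(outdir, f"snps_{a}_vs_{b}.tsv")
            snpcall.write_pairwise_tsv(all_calls[a], all_calls[b], a, b, reference, p, mode)
            pair_files.append(p)
    counts = snpcall.pairwise_count_table(all_calls, reference, mode)
    counts_path = os.path.join(outdir, "pairwise_counts.tsv")
    counts.to_csv(counts_path, sep="\t")
    return {
        "n_loci": len(matrix.loci),
        "matrix": matrix_path,
        "pairwise_counts": counts_path,
        "pairwise_files": pair_files,
    }


def read_matrix_tsv(path: str | os.PathLike) -> snpcall.SnpMatrix:
    loci: list[tuple[str, int, str]] = []
    alleles: list[list[str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[2:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ref_id, pos = fields[0], int(fields[1])
            row = fields[2:]
            loci.append((ref_id, pos, row[0]))  # reference column first
            alleles.append(row)
    return snpcall.SnpMatrix(loci=loci, samples=samples, alleles=alleles)


def stage_stats(matrix_path: str, outdir: str, include_reference: bool = True) -> dict:
    os.makedirs(outdir, exist_ok=True)
    matrix = read_matrix_tsv(matrix_path)
    stats = markerstats.marker_stats_table(matrix, include_reference=include_reference)
    stats_path = os.path.join(outdir, "marker_stats.tsv")
    stats.to_csv(stats_path, sep="\t", index=False)
    called_path = os.path.join(outdir, "called_allele_data.tsv")
    snpcall.write_called_allele_data(matrix, stats, called_path)
    return {"n_loci": len(matrix.loci), "stats": stats_path, "called_allele_data": called_path}


def stage_assay(
    matrix_path: str,
    reference: Sequence[ReferenceSequence],
    params: assaydesign.AssayParams,
    outdir: str,
    min_pic: float | None = None,
) -> dict:
    """Screen matrix loci per platform and write KASP/ADT/GFF3 outputs.

    ``min_pic`` optionally drops less informative loci (PIC below the
    threshold, computed over the full panel) before screening.
    """
    os.makedirs(outdir, exist_ok=True)
    matrix = read_matrix_tsv(matrix_path)
    if min_pic is not None:
        stats = markerstats.marker_stats_table(matrix)
        keep = {
            (r, p)
            for (r, p), pic in zip(zip(stats["ref_id"], stats["pos"]), stats["pic"])
            if pic is not None and pic >= min_pic
        }
        idx = [i for i, (r, p, _) in enumerate(matrix.loci) if (r, p) in keep]
        matrix = snpcall.SnpMatrix(
            loci=[matrix.loci[i] for i in idx],
            samples=matrix.samples,
            alleles=[matrix.alleles[i] for i in idx],
        )
    kasp = assaydesign.screen_matrix(matrix, reference, params, "KASP")
    adt = assaydesign.screen_matrix(matrix, reference, params, "Illumina")
    kasp_path = os.path.join(outdir, "kasp_input.tsv")
    adt_path = os.path.join(outdir, "adt_input.csv")
    gff_path = os.path.join(outdir, "snps.gff3")
    n_kasp = assaydesign.write_kasp_input(kasp, kasp_path)
    n_adt = assaydesign.write_adt_input(adt, adt_path)
    assaydesign.write_gff3_snps(matrix, gff_path)
    return {
        "kasp_pass": n_kasp,
        "adt_pass": n_adt,
        "kasp": kasp_path,
        "adt": adt_path,
        "gff3": gff_path,
    }


# ------------------------------------------------------------- full run

def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the run report (also written as
    ``report.json`` in the output directory)."""
    os.makedirs(config.outdir, exist_ok=True)
    stages_log = os.path.join(config.outdir, "stages.log")
    report: dict = {"samples": [s.name for s in config.samples], "stages": {}}

    def done(stage: str) -> None:
        with open(stages_log, "a") as fh:
            fh.write(stage + "\n")

    open(stages_log, "w").close()
    current = "import"
    try:
        reference = read_fasta(config.reference)
        done(current)

        if config.run_preprocess:
            current = "preprocess"
            report["stages"]["preprocess"] = [
                stage_preprocess(s.fastq, config.preprocess_params, config.outdir, s.name)
                for s in config.samples
                if s.fastq
            ]
            done(current)

        current = "call"
        candidates: set[tuple[str, int]] | None = None
        if config.snp_mode == "vcf":
            candidates = set()
            for s in config.samples:
                if s.vcf:
                    for ref_id, pos, _ref, _alts in read_vcf_candidates(s.vcf):
                        candidates.add((ref_id, pos))
        consensus_paths: dict[str, str] = {}
        call_reports = []
        for s in config.samples:
            out = os.path.join(config.outdir, f"consensus_{s.name}.tsv")
            call_reports.append(
                stage_call(
                    s.sam, reference, config.pileup_params, config.consensus_params,
                    out, candidate_positions=candidates,
                )
            )
            consensus_paths[s.name] = out
        report["stages"]["call"] = call_reports
        done(current)

        current = "matrix"
        report["stages"]["matrix"] = stage_matrix(
            consensus_paths, reference, config.comparison_mode, config.outdir
        )
        done(current)

        current = "stats"
        report["stages"]["stats"] = stage_stats(
            report["stages"]["matrix"]["matrix"],
            config.outdir,
            include_reference=config.include_reference_in_stats,
        )
        done(current)

        current = "assay"
        report["stages"]["assay"] = stage_assay(
            report["stages"]["matrix"]["matrix"],
            reference,
            config.assay_params,
            config.outdir,
            min_pic=config.min_pic,
        )
        done(current)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(current, exc) from exc

    # report.json holds paths relative to the output directory so that two
    # identical runs into different directories are byte-identical
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(_relativize(report, config.outdir), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _relativize(obj, root: str):
    if isinstance(obj, dict):
        return {k: _relativize(v, root) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_relativize(v, root) for v in obj]
    if isinstance(obj, str):
        absolute = os.path.abspath(obj)
        if absolute.startswith(os.path.abspath(root) + os.sep):
            return os.path.relpath(absolute, root)
    return obj
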