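# Methods

## Scope and data model

The package operates strictly downstream of alignment: inputs are Sanger
(phred+33) FASTQ, a FASTA reference, per-sample SAM alignments from any
external aligner, and optionally per-sample VCF candidate lists to be
confirmed. All public coordinates are 1-based inclusive (SAM/VCF/GFF3
convention). Only substitution SNPs are modelled; indels in alignments are
handled (CIGAR D/N leave reference positions uncounted, I/S consume query
silently) but never called.

Only phred+33 FASTQ is accepted and never rescaled: the Q20 rules below
are meaningless on silently rescaled Illumina 1.3/1.5 scores. The
rejection heuristic is any quality above 41 (under `strict_sanger`, on by
default) — Sanger/Illumina-1.8 data does not produce them, older Illumina
encodings decode far above. SAM files without headers (as produced by
Map→SAM converters) are accepted; reference names and lengths are then
taken from the FASTA.

## Pre-processing

Parameters, with units and defaults:

| parameter | default | meaning |
|---|---|---|
| `base_qual_min` | 20 phred | a base below this is low-quality (strict `<`) |
| `max_lowqual_fraction` | 0.30 | read discarded when low-quality fraction strictly exceeds this |
| `trim_offset` | 3 phred | trim threshold T = dataset mean − offset |
| `jump_margin` | 1 phred | boundary = first inward position with mean ≥ T + margin |

Both inequalities are deliberately strict: a read with exactly 30 %
low-quality bases is kept, a base at exactly Q20 is low-quality in the
read filter, and (separately, in the pileup) a base at exactly Q20 is
excluded from stacks by the strict `>20` rule. The two Q20 rules point in
different directions by design; both are parameterized.

The positional quality profile is computed over filter-surviving reads
only (filtering precedes trimming), per input file, and positions beyond
a shorter read's length are averaged over the reads covering them. One
trim window per input file is applied uniformly to all its reads — this
mirrors the observation that fixed post-trim lengths per file are the
natural product of a dataset-level trim decision, and keeps mate files
independently trimmable before pair synchronization.

The "sudden change" boundary is operationalized as: scanning inward, the
window boundary is the *first position whose mean phred reaches
T + jump_margin*; everything outside is trimmed. Positions with means in
the band [T, T + margin) are treated as still degraded. Other readings of
a jump-detection rule exist (e.g. first difference between adjacent
positions exceeding the margin); this one is monotone, needs no
look-ahead, and reproduces the intended behaviour on profiles degraded at
either or both ends, so it is the documented, parameterized choice.
A uniformly high profile yields the identity window; a dataset whose
profile never reaches the threshold raises an error rather than emitting
empty reads.

Whether the dataset mean should be pooled across a sample's files is
arguable; it is computed per file here, consistent with the per-file
window.

## Pileup and consensus

The stack at a position is the count vector over {A,C,G,T} of aligned
query bases from CIGAR match columns (M/=/X) with phred strictly above
`stack_qual_min` (20) and record MAPQ ≥ `mapq_min` (0 = off, exposed for
parity with common practice but not part of the core method). N bases
never count. Both mates of an overlapping pair are counted — no
de-duplication of overlapping coverage is attempted, and this is a known
source of optimism in paired data.

Consensus: with depth d < `min_depth` (default 3) the position is
missing. Otherwise f = max count / d; f ≥ `f_major` (0.66) gives the
major base, else the top two bases become an IUPAC heterozygote code.
Boundary semantics: f equal to the threshold counts as major, so the
printed 0.66 behaves as 2/3 on a depth-3 stack — with strict `>` a
depth-3 stack could never be called at the default threshold, which would
make `min_depth=3` self-defeating. Ties are deterministic: bases are
ranked by count descending then alphabetically, so an equal-count top
pair always produces the same ambiguity code. The depth gate of 3 is a
floor, not a recommendation; it is a required, logged parameter.

VCF-candidate mode does not reimplement samtools/bcftools: an existing
VCF supplies candidate positions (SNP records only; indels/MNPs skipped
and counted), each candidate is re-called per sample from its quality
stack exactly as above, and candidates where no sample's non-missing call
differs from the reference allele are dropped. In the staged pipeline the
restriction happens at the calling stage and the cross-sample drop falls
out of matrix construction, which is equivalent.

## SNP comparison, matrix, statistics

Strict mode (default) reports a position iff both samples carry
unambiguous major calls that differ — the high-confidence set. Lenient
mode also compares heterozygote codes but suppresses *nested* allele-set
pairs (A vs R): a nested pair may share an allele, so calling it a SNP
would overstate the evidence. Missing never compares. How ambiguity codes
should be compared across genotypes is genuinely open; providing both
modes, strict by default, is the package's resolution.

The matrix is the union of all pairwise and vs-reference SNP positions
(reference-N positions excluded), sorted by (ref_id, pos), with the
reference as the first pseudo-sample column and `-` for missing. The
pairwise count table carries a reference row, is symmetric and
zero-diagonal by construction.

Allele frequencies use copy counting (homozygote 2, heterozygote 1 per
constituent, missing 0) — a diploid reading of the call symbols; the
frequency panel includes the reference column by default (configurable),
treating the reference as one more genotype of the germplasm set. PIC is
the full Botstein et al. (1980) form 1 − Σp² − Σᵢ<ⱼ2pᵢ²pⱼ², reported
alongside He = 1 − Σp² so the two informativeness measures are never
conflated; PIC ≤ He algebraically, both are 0 for monomorphic loci and
peak at 0.375 / 0.5 for balanced biallelic loci. MAF is the
second-largest frequency, 0 if monomorphic.

## Assay screening

Flank lengths default to 50 bp (KASP) and 60 bp (Illumina ADT) — platform
convention, configurable, and the only point where the two outputs
differ. The co-sited-SNP criterion is evaluated against the *full*
non-redundant locus set, not only the pair being compared: a probe must
avoid every known variable site. The assay allele pair is the reference
allele first, then the most frequent alternative in the panel. The exact
ADT column layout is not standardized publicly; the CSV written here
(Locus_Name, Target_Type, Sequence, Chromosome, Coordinate) is documented
as this package's layout. A `min_pic` option drops uninformative loci
before screening rather than hard-filtering by default.

## Simulator

The generator emulates: uniform random references; biallelic SNPs planted
at least `end_margin` (default: one read length) from sequence ends, with
per-sample independent genotypes (het with probability `het_fraction`,
else hom-alt with `alt_prob` = 0.5); uniform read starts to an expected
fold-coverage; per-cycle mean qualities with optional linear 3′ decay and
integer jitter; uniform substitution errors. Reads are emitted with
*truth-placement* SAM records (full-match CIGAR at the drawn position),
so no aligner is needed and alignment error is zero by construction.

It does **not** emulate: indels, alignment/mapping error, reference bias,
duplicate reads, GC- or motif-dependent error spectra, quality
miscalibration, or RAD-style locus dropout. Passing tests therefore
demonstrate correctness of the counting, calling, matrix and export
machinery under ideal alignment — not robustness to mapping artefacts,
which belongs to the upstream aligner.

All randomness flows from one integer seed through spawned NumPy
generators (reference / variants / reads), so every artefact is
reproducible byte-for-byte from the config.

## Validation sizes and numerical choices

The validation study uses a 100 kb reference, 2 samples, 200 planted
homozygous SNPs at 30× coverage — large enough that every per-position
depth is comfortably past the gate (Poisson mean 30) while a full
replicate runs in seconds on one core; the noisy replicate uses 0.5 %
substitution error, an upper bound for modern Illumina data after Q20
stack filtering. Recall/precision are measured on truth positions with
depth ≥ 3 in both samples, matching the caller's own visibility. Smaller
end-to-end fixtures (10–50 kb, 20–30× coverage) exercise reproducibility
and CLI chaining.

Degenerate inputs are errors, not silent results: empty post-filter read
sets, all-trimmed profiles, all-missing matrix rows (per-locus NaN in the
stats table when the reference column is excluded), duplicate FASTA ids,
duplicate read ids within a mate file. Malformed SAM records are counted
and skipped by default (strict mode aborts), so one bad record does not
kill a multi-gigabyte run. Byte-identical reruns are guaranteed by
writing only seed-derived content and relative paths into reports.

## Known limitations

- No BAM/CRAM; SAM text only (by design — the deliverable is auditable
  flat text).
- No overlapping-mate de-counting, BAQ, or duplicate marking.
- No indel calling or imputation of missing genotypes.
- Pairwise comparison of heterozygote calls is heuristic (see lenient
  mode); strict mode simply refuses to compare them.
- The CbCC depth gate and the Illumina/KASP flank lengths are
  conventions, not measured optima; both are parameters.
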