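"""Seeded synthetic-data generators for every fixture the toolkit consumes:
toy references, deletion-bearing observed sequences with planted
microhomology, two-haplotype paired-read sets with known phase, and
amplicon-pool read sets for depth QC.

Reads are emitted as already-aligned records (their coordinates and CIGAR
strings are known by construction), so tests and demos need no external
aligner; FASTQ export is available for users who want to run one. Defaults
mirror the sequencing protocol being emulated: 2x151 bp paired-end reads
from ~375 +/- 25 bp sheared fragments. The error model is substitution-only,
which keeps phasing and breakpoint truth unambiguous.

Identical (seed, scenario) inputs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pysam

from .intervals import GenomicInterval, ValidationError
from .panel import AmpliconPanel

_BASES = np.array(list("ACGT"))
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}

DEFAULT_READ_LENGTH = 151
DEFAULT_INSERT_MEAN = 375
DEFAULT_INSERT_SD = 25


@dataclass(frozen=True)
class SimulationScenario:
    """Knobs shared by the read simulators."""

    seed: int = 0
    read_length: int = DEFAULT_READ_LENGTH
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD
    depth: float = 50.0
    error_rate: float = 0.0

    def with_(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# references


def make_reference(length: int, seed: int) -> str:
    """Uniform-random A/C/G/T sequence of the given length."""
    if length <= 0:
        raise ValidationError(f"reference length must be > 0, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=length))


def write_fasta(path: str, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Read a (small, plain-text) FASTA file into {name: sequence}."""
    with pysam.FastxFile(path) as fx:
        return {entry.name: (entry.sequence or "").upper() for entry in fx}


# ---------------------------------------------------------------------------
# planted deletions


@dataclass(frozen=True)
class DeletionTruth:
    """Ground truth for one planted deletion."""

    contig: str
    start: int  # 1-based, leftmost placement
    length: int
    mh_len: int
    mh_seq: str
    placements: tuple[tuple[int, int], ...]  # all equivalent (start, end) pairs


def plant_deletion(
    reference: str,
    start: int,
    length: int,
    mh_len: int = 0,
    contig: str = "toy",
) -> tuple[str, str, DeletionTruth]:
    """Plant a deletion with an exactly ``mh_len``-long microhomology.

    The 3' flank is rewritten so its first ``mh_len`` bases equal the first
    ``mh_len`` bases of the deleted segment, then the bases just beyond the
    homology on both sides are forced to mismatch so chance extension cannot
    enlarge the placement set. Returns (mutated reference, observed sequence
    after deletion, truth record); the truth placement set has exactly
    ``mh_len + 1`` entries.
    """
    if start < 1 or length < 1 or mh_len < 0:
        raise ValidationError("start, length must be >= 1 and mh_len >= 0")
    if start + length + mh_len > len(reference):
        raise ValidationError(
            "deletion + microhomology (plus one pinning base) must fit "
            "within the reference"
        )
    seq = list(reference.upper())
    d = start - 1  # 0-based deletion start
    for j in range(mh_len):
        seq[d + length + j] = seq[d + j]
    # pin the right boundary: first base past the homology must mismatch
    if seq[d + length + mh_len] == seq[d + mh_len]:
        seq[d + length + mh_len] = _NEXT_BASE[seq[d + mh_len]]
    # pin the left boundary: base before the deletion must mismatch its
    # counterpart before the 3' flank
    if d >= 1 and seq[d - 1] == seq[d + length - 1]:
        seq[d - 1] = _NEXT_BASE[seq[d + length - 1]]
    mutated = "".join(seq)
    observed = mutated[:d] + mutated[d + length :]
    mh_seq = mutated[d : d + mh_len]
    placements = tuple(
        (start + k, start + k + length - 1) for k in range(mh_len + 1)
    )
    truth = DeletionTruth(contig, start, length, mh_len, mh_seq, placements)
    return mutated, observed, truth


# ---------------------------------------------------------------------------
# haplotypes and coordinate maps

Variant = tuple[int, str, str]  # (1-based pos, ref allele, alt allele)


def apply_variants(reference: str, variants: Sequence[Variant]) -> tuple[str, list[int]]:
    """Apply VCF-style variants to a reference.

    Returns the haplotype sequence and a map ``hap2ref`` giving, for every
    haplotype position, the 0-based reference position it aligns to, or -1
    for inserted bases. Variants must be sorted, non-overlapping and within
    the reference.
    """
    hap: list[str] = []
    hap2ref: list[int] = []
    cursor = 0
    last_end = 0
    for pos, ref_a, alt_a in sorted(variants):
        p0 = pos - 1
        if p0 < last_end:
            raise ValidationError(f"overlapping variants near position {pos}")
        if p0 + len(ref_a) > len(reference):
            raise ValidationError(f"variant at {pos} outside reference")
        if reference[p0 : p0 + len(ref_a)].upper() != ref_a.upper():
            raise ValidationError(
                f"variant at {pos}: stated ref allele {ref_a!r} does not "
                "match the reference sequence"
            )
        hap.extend(reference[cursor:p0])
        hap2ref.extend(range(cursor, p0))
        for i, base in enumerate(alt_a):
            hap.append(base)
            hap2ref.append(p0 + i if i < len(ref_a) else -1)
        cursor = p0 + len(ref_a)
        last_end = cursor
    hap.extend(reference[cursor:])
    hap2ref.extend(range(cursor, len(reference)))
    return "".join(hap), hap2ref


def _cigar_from_map(hap2ref: Sequence[int], s: int, e: int) -> tuple[int, list[tuple[int, int]]]:
    """(reference_start, cigartuples) for the haplotype slice [s, e)."""
    M, I, D = 0, 1, 2
    ops: list[tuple[int, int]] = []

    def push(op: int, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    ref_start = -1
    prev_ref = None
    for idx in range(s, e):
        r = hap2ref[idx]
        if r < 0:
            push(I, 1)
            continue
        if ref_start < 0:
            ref_start = r
        if prev_ref is not None and r > prev_ref + 1:
            push(D, r - prev_ref - 1)
        push(M, 1)
        prev_ref = r
    if ref_start < 0:
        raise ValidationError("read lies entirely within an insertion")
    # a leading insertion has no anchor; soft-clip it instead
    if ops and ops[0][0] == I:
        ops[0] = (4, ops[0][1])  # S
    if ops and ops[-1][0] == I:
        ops[-1] = (4, ops[-1][1])
    return ref_start, ops


# ---------------------------------------------------------------------------
# paired-read simulation over two haplotypes


@dataclass
class FragmentSet:
    """Simulated aligned reads plus their ground truth."""

    header: pysam.AlignmentHeader
    records: list[pysam.AlignedSegment]
    truth_haplotype: dict[str, int] = field(default_factory=dict)

    def write_sam(self, path: str) -> None:
        write_sam(path, self.header, self.records)

    def write_truth_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("fragment_id\thaplotype\n")
            for name in sorted(self.truth_haplotype):
                fh.write(f"{name}\t{self.truth_haplotype[name]}\n")


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < error_rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _segment(
    name: str,
    contig: str,
    header: pysam.AlignmentHeader,
    hap2ref: Sequence[int],
    hap_seq: str,
    s: int,
    e: int,
    rng: np.random.Generator,
    error_rate: float,
    flag: int,
) -> pysam.AlignedSegment:
    ref_start, cigar = _cigar_from_map(hap2ref, s, e)
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_name = contig
    seg.reference_start = ref_start
    seg.mapping_quality = 60
    seg.cigartuples = cigar
    seg.flag = flag
    seg.query_sequence = _apply_errors(hap_seq[s:e], rng, error_rate)
    seg.query_qualities = pysam.qualitystring_to_array("I" * (e - s))
    return seg


def simulate_fragments(
    reference: str,
    haplotype_variants: tuple[Sequence[Variant], Sequence[Variant]],
    scenario: SimulationScenario,
    contig: str = "sim",
) -> FragmentSet:
    """Paired 2x``read_length`` reads drawn equally from two haplotypes.

    Fragment (insert) sizes follow a normal distribution truncated to
    [read_length, haplotype length]; per-base substitution errors occur at
    ``scenario.error_rate``. The truth table records each fragment's
    haplotype of origin. Coverage ``depth`` is in fold-coverage of the
    reference.
    """
    for variants in haplotype_variants:
        for pos, ref_a, _alt in variants:
            if pos < 1 or pos - 1 + len(ref_a) > len(reference):
                raise ValidationError(f"variant at {pos} outside reference")
    rng = np.random.default_rng(scenario.seed)
    haps = [apply_variants(reference, v) for v in haplotype_variants]
    header = pysam.AlignmentHeader.from_references([contig], [len(reference)])
    rl = scenario.read_length
    n_frags = int(round(scenario.depth * len(reference) / (2 * rl)))
    records: list[pysam.AlignedSegment] = []
    truth: dict[str, int] = {}
    for i in range(n_frags):
        h = int(rng.integers(2))
        hap_seq, hap2ref = haps[h]
        isize = int(round(rng.normal(scenario.insert_mean, scenario.insert_sd)))
        isize = max(rl, min(isize, len(hap_seq)))
        s = int(rng.integers(0, len(hap_seq) - isize + 1))
        name = f"frag{i:06d}"
        truth[name] = h
        # flags: 99/147 = properly paired, mates on opposite strands
        r1 = _segment(name, contig, header, hap2ref, hap_seq, s, s + rl,
                      rng, scenario.error_rate, flag=99)
        r2 = _segment(name, contig, header, hap2ref, hap_seq,
                      s + isize - rl, s + isize, rng, scenario.error_rate, flag=147)
        r1.next_reference_name = contig
        r1.next_reference_start = r2.reference_start
        r2.next_reference_name = contig
        r2.next_reference_start = r1.reference_start
        r1.template_length = isize
        r2.template_length = -isize
        records.extend([r1, r2])
    records.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
    return FragmentSet(header, records, truth)


def write_truth_vcf(
    path: str,
    contig: str,
    reference: str,
    haplotype_variants: tuple[Sequence[Variant], Sequence[Variant]],
    sample: str = "SIM",
) -> None:
    """Write the simulated variants as a genotyped VCF.

    Variants present on exactly one haplotype get genotype 0|1 (or 1|0);
    variants shared by both haplotypes are homozygous 1|1.
    """
    h0 = set(haplotype_variants[0])
    h1 = set(haplotype_variants[1])
    rows = []
    for pos, ref_a, alt_a in sorted(h0 | h1):
        in0, in1 = (pos, ref_a, alt_a) in h0, (pos, ref_a, alt_a) in h1
        gt = "1|1" if (in0 and in1) else ("1|0" if in0 else "0|1")
        rows.append((pos, ref_a, alt_a, gt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for pos, ref_a, alt_a, gt in rows:
            fh.write(f"{contig}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\tPASS\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# amplicon-pool simulation


def simulate_amplicon_pool(
    panel: AmpliconPanel,
    scenario: SimulationScenario,
    references: dict[str, str] | None = None,
    contig_lengths: dict[str, int] | None = None,
    mode: str = "random",
) -> FragmentSet:
    """Reads generated per amplicon independently at the scenario depth.

    Each amplicon contributes its own read set, so regions tiled by two
    amplicons receive summed (doubled) depth - the coverage signature of
    overlapping LR amplicons.

    ``mode="random"`` draws paired reads with random fragment positions
    (interior depth approximates the target with ramped amplicon edges);
    ``mode="uniform"`` lays ``depth`` successive end-to-end tilings of
    single reads (trimmed at amplicon boundaries), giving *exactly*
    ``depth`` at every amplicon base - the noiseless setting in which
    overlap regions show exactly summed depth.
    """
    if mode not in ("random", "uniform"):
        raise ValidationError(f"unknown mode {mode!r}")
    lengths: dict[str, int] = dict(contig_lengths or {})
    for loc in panel:
        need = max(a.interval.end for a in loc.amplicons)
        lengths[loc.contig] = max(lengths.get(loc.contig, 0), need)
    names = sorted(lengths)
    header = pysam.AlignmentHeader.from_references(
        names, [lengths[n] for n in names]
    )
    rng = np.random.default_rng(scenario.seed)
    rl = scenario.read_length
    records: list[pysam.AlignedSegment] = []

    def seq_for(contig: str, start0: int, length: int) -> str:
        if references and contig in references:
            return references[contig][start0 : start0 + length]
        return "A" * length

    def make_read(name: str, contig: str, start0: int, length: int, flag: int = 0):
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.reference_name = contig
        seg.reference_start = start0
        seg.mapping_quality = 60
        seg.cigartuples = [(0, length)]
        seg.flag = flag
        seg.query_sequence = _apply_errors(
            seq_for(contig, start0, length), rng, scenario.error_rate
        )
        seg.query_qualities = pysam.qualitystring_to_array("I" * length)
        return seg

    for loc in panel:
        for amp in loc.amplicons:
            iv = amp.interval
            lo0, hi0 = iv.start - 1, iv.end  # 0-based half-open
            if mode == "uniform":
                passes = int(round(scenario.depth))
                for p in range(passes):
                    pos = lo0
                    k = 0
                    while pos < hi0:
                        n = min(rl, hi0 - pos)
                        records.append(
                            make_read(f"{amp.name}_u{p}_{k}", iv.contig, pos, n)
                        )
                        pos += n
                        k += 1
            else:
                n_frags = int(
                    round(scenario.depth * len(iv) / (2 * rl))
                )
                for i in range(n_frags):
                    isize = int(
                        round(rng.normal(scenario.insert_mean, scenario.insert_sd))
                    )
                    isize = max(rl, min(isize, hi0 - lo0))
                    s = int(rng.integers(lo0, hi0 - isize + 1))
                    name = f"{amp.name}_f{i:06d}"
                    r1 = make_read(name, iv.contig, s, rl, flag=99)
                    r2 = make_read(name, iv.contig, s + isize - rl, rl, flag=147)
                    r1.next_reference_name = iv.contig
                    r1.next_reference_start = r2.reference_start
                    r2.next_reference_name = iv.contig
                    r2.next_reference_start = r1.reference_start
                    r1.template_length = isize
                    r2.template_length = -isize
                    records.extend([r1, r2])
    records.sort(
        key=lambda r: (r.reference_name or "", r.reference_start, r.query_name, r.flag)
    )
    return FragmentSet(header, records, {})


# ---------------------------------------------------------------------------
# output helpers


def write_sam(
    path: str, header: pysam.AlignmentHeader, records: Iterable[pysam.AlignedSegment]
) -> None:
    """Write records as plain-text SAM (coordinate order preserved)."""
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            out.write(rec)


def write_fastq(path: str, records: Iterable[pysam.AlignedSegment]) -> None:
    """FASTQ export for users who want to run a real aligner."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.query_sequence or ""
            qual = (
                pysam.qualities_to_qualitystring(rec.query_qualities)
                if rec.query_qualities is not None
                else "I" * len(seq)
            )
            suffix = "/1" if rec.is_read1 else ("/2" if rec.is_read2 else "")
            fh.write(f"@{rec.query_name}{suffix}\n{seq}\n+\n{qual}\n")
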