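"""Per-base depth profiling, low-coverage gap detection, and the
homozygous-run allele-dropout warning.

Depth counts aligned read bases (CIGAR-aware): a base deleted from a read
contributes no depth at the deleted reference positions, and inserted bases
consume no reference. Duplicate-flagged, secondary, supplementary and
unmapped records are excluded; no duplicate marking is performed here
(amplicon libraries are PCR-derived, duplicates are expected and kept
unless already flagged upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np
import pysam

from .intervals import GenomicInterval, ValidationError


@dataclass
class DepthProfile:
    """Per-base depth over a 1-based inclusive region."""

    contig: str
    start: int  # 1-based
    depths: np.ndarray  # int array, len == region length

    @property
    def end(self) -> int:
        return self.start + len(self.depths) - 1

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end)

    def depth_at(self, pos: int) -> int:
        if not (self.start <= pos <= self.end):
            raise IndexError(f"{pos} outside profiled region {self.region}")
        return int(self.depths[pos - self.start])

    def mean(self, interval: GenomicInterval | None = None) -> float:
        if interval is None:
            return float(self.depths.mean())
        sub = self.intersect(interval)
        return float(sub.mean()) if len(sub) else 0.0

    def intersect(self, interval: GenomicInterval) -> np.ndarray:
        if interval.contig != self.contig:
            return np.empty(0, dtype=self.depths.dtype)
        lo = max(interval.start, self.start) - self.start
        hi = min(interval.end, self.end) - self.start + 1
        return self.depths[lo:hi] if hi > lo else np.empty(0, dtype=self.depths.dtype)

    def to_tsv(self, handle: TextIO) -> None:
        handle.write("contig\tpos\tdepth\n")
        for i, d in enumerate(self.depths):
            handle.write(f"{self.contig}\t{self.start + i}\t{int(d)}\n")


def depth_profile(
    alignments: str | Iterable[pysam.AlignedSegment],
    region: GenomicInterval,
    min_mapq: int = 0,
) -> DepthProfile:
    """Per-base aligned-base depth over ``region``.

    Streams the alignment file (no index required); reads below ``min_mapq``
    are skipped entirely. Raises when the alignment header knows nothing
    about the region's contig.
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, check_sq=False) as af:
            if af.header.nreferences and region.contig not in af.references:
                raise ValidationError(
                    f"contig {region.contig!r} absent from alignment header"
                )
            reads = [r for r in af]
    else:
        reads = list(alignments)
    depths = np.zeros(len(region), dtype=np.int64)
    lo0, hi0 = region.start - 1, region.end  # 0-based half-open
    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.reference_name != region.contig
            or read.mapping_quality < min_mapq
        ):
            continue
        if read.reference_end is None or read.reference_end <= lo0 or read.reference_start >= hi0:
            continue
        for rpos in read.get_reference_positions():
            if lo0 <= rpos < hi0:
                depths[rpos - lo0] += 1
    return DepthProfile(region.contig, region.start, depths)


def gap_report(profile: DepthProfile, min_depth: int = 20) -> list[GenomicInterval]:
    """Maximal intervals of the profiled region with depth below threshold."""
    below = profile.depths < min_depth
    gaps: list[GenomicInterval] = []
    run_start: int | None = None
    for i, flag in enumerate(below):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            gaps.append(
                GenomicInterval(profile.contig, profile.start + run_start, profile.start + i - 1)
            )
            run_start = None
    if run_start is not None:
        gaps.append(
            GenomicInterval(profile.contig, profile.start + run_start, profile.end)
        )
    return gaps


@dataclass(frozen=True)
class HomozygosityWarning:
    """All variant calls in a region are homozygous: possible allele dropout.

    A deletion spanning a primer-binding site silently removes one allele
    from the PCR; the surviving allele then genotypes as homozygous at every
    variant position. A run of exclusively homozygous-appearing calls is
    therefore a deletion/ADO signature worth flagging, especially in
    non-consanguineous families.
    """

    region: GenomicInterval
    n_hom: int

    def __str__(self) -> str:
        return (
            f"WARNING: all {self.n_hom} variant calls in {self.region} are "
            "homozygous - possible allele dropout or heterozygous deletion"
        )


def homozygosity_warning(
    vcf_path: str,
    region: GenomicInterval,
    min_sites: int = 5,
    sample: str | None = None,
) -> HomozygosityWarning | None:
    """Warn when a region's variant calls are 100% homozygous.

    Returns None when fewer than ``min_sites`` calls fall in the region or
    when at least one heterozygous call is present.
    """
    n_hom = 0
    n_het = 0
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValidationError(f"{vcf_path} carries no genotype columns")
        use = sample or samples[0]
        for rec in vcf:
            if rec.contig != region.contig or not (region.start <= rec.pos <= region.end):
                continue
            gt = [a for a in rec.samples[use].get("GT", ()) if a is not None]
            if len(gt) < 2:
                continue
            if gt[0] == gt[1]:
                if gt[0] != 0:  # hom-alt call
                    n_hom += 1
            else:
                n_het += 1
    if n_het == 0 and n_hom >= min_sites:
        return HomozygosityWarning(region, n_hom)
    return None
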