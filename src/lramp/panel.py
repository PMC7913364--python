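"""Amplicon-panel data model: loci, amplicons, primer sites, and the
target-size / gap / overlap / allele-dropout accounting they support.

A long-range (LR) PCR panel tiles each locus of interest (gene body plus
introns and promoter) with amplicons of roughly 4-20 kb. Amplicons of
adjacent regions overlap, so per-locus genomic target size is the size of
the *union* of its amplicon intervals, and regions covered by two or more
amplicons show doubled read depth downstream.

Panel files are BED6+ TSV (0-based half-open, per BED convention); all
in-memory coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .intervals import (
    GenomicInterval,
    ValidationError,
    complement_within,
    depth_at_least,
    merge_intervals,
    union_size,
)


@dataclass(frozen=True)
class Amplicon:
    """One LR PCR product: its genomic span and primer-binding sites.

    Primer sites are optional (None when the panel file does not record
    them); when present they must lie at the two ends of, and within, the
    amplicon interval.
    """

    name: str
    interval: GenomicInterval
    fwd_primer_site: GenomicInterval | None = None
    rev_primer_site: GenomicInterval | None = None

    def __post_init__(self) -> None:
        for site, label in (
            (self.fwd_primer_site, "fwd"),
            (self.rev_primer_site, "rev"),
        ):
            if site is not None and not self.interval.contains(site):
                raise ValidationError(
                    f"{label} primer site {site} outside amplicon "
                    f"{self.name} ({self.interval})"
                )
        if self.fwd_primer_site is not None and self.fwd_primer_site.start != self.interval.start:
            raise ValidationError(
                f"fwd primer of {self.name} does not start at the amplicon 5' end"
            )
        if self.rev_primer_site is not None and self.rev_primer_site.end != self.interval.end:
            raise ValidationError(
                f"rev primer of {self.name} does not end at the amplicon 3' end"
            )

    @property
    def product_size_bp(self) -> int:
        return len(self.interval)

    @property
    def has_primer_sites(self) -> bool:
        return self.fwd_primer_site is not None and self.rev_primer_site is not None


@dataclass(frozen=True)
class Locus:
    """A named locus and its ordered amplicon tiling."""

    name: str
    amplicons: tuple[Amplicon, ...]
    target: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.amplicons:
            raise ValidationError(f"locus {self.name} has no amplicons")
        contigs = {a.interval.contig for a in self.amplicons}
        if len(contigs) != 1:
            raise ValidationError(
                f"locus {self.name} spans multiple contigs: {sorted(contigs)}"
            )
        object.__setattr__(
            self,
            "amplicons",
            tuple(sorted(self.amplicons, key=lambda a: (a.interval.start, a.interval.end))),
        )
        if self.target is None:
            merged = merge_intervals(a.interval for a in self.amplicons)
            object.__setattr__(
                self,
                "target",
                GenomicInterval(merged[0].contig, merged[0].start, merged[-1].end),
            )

    @property
    def contig(self) -> str:
        return self.amplicons[0].interval.contig

    @property
    def span(self) -> GenomicInterval:
        assert self.target is not None
        return self.target


@dataclass
class AmpliconPanel:
    """A collection of loci; loci on the same contig must not overlap."""

    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate locus names: {dupes}")
        spans = sorted(
            (loc.span for loc in self.loci), key=lambda s: (s.contig, s.start)
        )
        for a, b in zip(spans, spans[1:]):
            if a.intersects(b):
                raise ValidationError(
                    f"loci overlap: {a} and {b} (ambiguous target attribution)"
                )

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    @property
    def contigs(self) -> set[str]:
        return {loc.contig for loc in self.loci}


# ---------------------------------------------------------------------------
# size / gap / overlap accounting


def locus_target_size(locus: Locus) -> int:
    """Genomic target size of a locus: bases covered by >=1 amplicon.

    Overlapping stretches of adjacent amplicons are counted once.
    """
    return union_size(a.interval for a in locus.amplicons)


def panel_target_size(panel: AmpliconPanel) -> int:
    """Total genomic target of the panel (loci are disjoint by invariant)."""
    return sum(locus_target_size(loc) for loc in panel.loci)


def find_gaps(locus: Locus) -> list[GenomicInterval]:
    """Maximal intervals of ``locus.target`` covered by no amplicon."""
    return complement_within(locus.span, [a.interval for a in locus.amplicons])


def overlap_regions(locus: Locus) -> list[GenomicInterval]:
    """Maximal intervals covered by two or more amplicons."""
    return depth_at_least([a.interval for a in locus.amplicons], 2)


# ---------------------------------------------------------------------------
# allele-dropout risk


@dataclass(frozen=True)
class AdoFlag:
    """One allele-dropout finding for one amplicon."""

    locus: str
    amplicon: str
    reason: str  # "fwd_primer", "rev_primer", "amplicon_contained", "end_overlap"
    detail: str


@dataclass
class AdoReport:
    """ADO risk assessment for a candidate deletion against the panel.

    A deletion that removes a primer-binding site prevents amplification of
    the deleted allele: the assay then shows no sign of the CNV beyond
    reduced PCR yield and exclusively homozygous-appearing variants. A
    deletion strictly internal to an amplicon (touching no primer site) is
    detectable from the sequencing data itself.
    """

    deletion: GenomicInterval
    flags: list[AdoFlag]
    primer_sites_known: bool

    @property
    def at_risk(self) -> bool:
        return any(
            f.reason in ("fwd_primer", "rev_primer", "end_overlap") for f in self.flags
        )

    def summary(self) -> str:
        if not self.flags:
            return "detectable, no ADO risk"
        lines = []
        if not self.primer_sites_known:
            lines.append(
                "warning: primer spans unknown; flagging amplicons whose ends "
                "intersect the deletion"
            )
        for f in self.flags:
            lines.append(f"{f.locus}/{f.amplicon}: {f.reason} ({f.detail})")
        return "\n".join(lines)


def ado_risk(panel: AmpliconPanel, deletion: GenomicInterval) -> AdoReport:
    """Flag amplicons whose primer sites the deletion removes.

    Amplicons fully contained in the deletion are flagged as well (the whole
    product is lost on the deleted allele). When the panel records no primer
    spans the check degrades to the amplicon end coordinates, with a warning
    recorded on the report.
    """
    if deletion.contig not in panel.contigs:
        raise ValidationError(
            f"deletion contig {deletion.contig!r} not present in panel"
        )
    flags: list[AdoFlag] = []
    any_primers = any(a.has_primer_sites for loc in panel for a in loc.amplicons)
    for loc in panel:
        for amp in loc.amplicons:
            if not amp.interval.intersects(deletion):
                continue
            if deletion.contains(amp.interval):
                flags.append(
                    AdoFlag(loc.name, amp.name, "amplicon_contained",
                            f"amplicon {amp.interval} within deletion")
                )
                continue
            if amp.has_primer_sites:
                assert amp.fwd_primer_site is not None
                assert amp.rev_primer_site is not None
                if amp.fwd_primer_site.intersects(deletion):
                    flags.append(
                        AdoFlag(loc.name, amp.name, "fwd_primer",
                                f"deletion hits {amp.fwd_primer_site}")
                    )
                if amp.rev_primer_site.intersects(deletion):
                    flags.append(
                        AdoFlag(loc.name, amp.name, "rev_primer",
                                f"deletion hits {amp.rev_primer_site}")
                    )
            else:
                # degraded mode: amplicon termini stand in for primer spans
                if deletion.start <= amp.interval.start <= deletion.end or \
                        deletion.start <= amp.interval.end <= deletion.end:
                    flags.append(
                        AdoFlag(loc.name, amp.name, "end_overlap",
                                "deletion reaches an amplicon end; primer spans unknown")
                    )
    return AdoReport(deletion=deletion, flags=flags, primer_sites_known=any_primers)


# ---------------------------------------------------------------------------
# BED6+ I/O
#
# Columns: contig, start (0-based), end (half-open), locus, amplicon, score
# placeholder, optional fwd/rev primer spans as 1-based "start-end" strings.

_PRIMER_RE = re.compile(r"^(\d+)-(\d+)$")


class PanelParseError(ValidationError):
    pass


def _parse_primer_span(text: str, contig: str, lineno: int) -> GenomicInterval:
    m = _PRIMER_RE.match(text.strip())
    if m is None:
        raise PanelParseError(f"line {lineno}: bad primer span {text!r}")
    return GenomicInterval(contig, int(m.group(1)), int(m.group(2)))


def load_panel(path_or_handle: str | TextIO) -> AmpliconPanel:
    """Read a BED6+ panel definition into an :class:`AmpliconPanel`.

    BED coordinates (0-based half-open) are converted to 1-based inclusive
    at this boundary; primer-span columns, when present, are already
    1-based inclusive. Comment lines start with ``#``; an empty file yields
    an empty panel.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return load_panel(fh)
    rows_by_locus: dict[str, list[Amplicon]] = {}
    for lineno, raw in enumerate(path_or_handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise PanelParseError(
                f"line {lineno}: expected >=5 tab-separated columns, got {len(fields)}"
            )
        contig, bed_start, bed_end, locus_name, amp_name = fields[:5]
        try:
            start0, end0 = int(bed_start), int(bed_end)
        except ValueError as exc:
            raise PanelParseError(f"line {lineno}: non-integer coordinate") from exc
        if end0 <= start0:
            raise PanelParseError(
                f"line {lineno}: end ({end0}) <= start ({start0})"
            )
        interval = GenomicInterval(contig, start0 + 1, end0)
        fwd = rev = None
        if len(fields) >= 8 and fields[6].strip():
            fwd = _parse_primer_span(fields[6], contig, lineno)
        if len(fields) >= 8 and fields[7].strip():
            rev = _parse_primer_span(fields[7], contig, lineno)
        try:
            amp = Amplicon(amp_name, interval, fwd, rev)
        except ValidationError as exc:
            raise PanelParseError(f"line {lineno}: {exc}") from exc
        rows_by_locus.setdefault(locus_name, []).append(amp)
    loci = [Locus(name, tuple(amps)) for name, amps in rows_by_locus.items()]
    return AmpliconPanel(loci=loci)


def write_panel(panel: AmpliconPanel, path_or_handle: str | TextIO) -> None:
    """Write a panel back to BED6+ TSV (inverse of :func:`load_panel`)."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_panel(panel, fh)
            return
    fh = path_or_handle
    fh.write("#contig\tstart\tend\tlocus\tamplicon\tscore\tfwd_primer\trev_primer\n")
    for loc in panel:
        for amp in loc.amplicons:
            iv = amp.interval
            fwd = (
                f"{amp.fwd_primer_site.start}-{amp.fwd_primer_site.end}"
                if amp.fwd_primer_site
                else ""
            )
            rev = (
                f"{amp.rev_primer_site.start}-{amp.rev_primer_site.end}"
                if amp.rev_primer_site
                else ""
            )
            fh.write(
                f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{loc.name}\t{amp.name}\t0\t{fwd}\t{rev}\n"
            )


def gap_report_rows(panel: AmpliconPanel) -> Iterable[tuple[str, str, int, int, int]]:
    """Rows (locus, contig, start, end, length) for every coverage gap."""
    for loc in panel:
        for gap in find_gaps(loc):
            yield loc.name, gap.contig, gap.start, gap.end, len(gap)
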