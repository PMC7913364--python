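"""Deletion-breakpoint characterization from a reference/observed sequence
comparison: exact deletion length, flanking microhomology, the set of
equivalent breakpoint placements, and HGVS g. rendering (exact or
ambiguous-interval form).

A deletion whose flanks share a short identical sequence (microhomology)
cannot be placed uniquely: if the reference carries ``...P-M-deleted-M-S...``
with M the shared m-mer, removing any of m+1 shifted windows yields the same
observed sequence. This module computes that placement set from longest
common prefix/suffix (LCP/LCS) algebra: with reference length R, observed
length O, LCP length p and LCS length s, the event is a single clean
deletion iff p + s >= O, the microhomology length is m = p + s - O, and the
deletion may start at any of the m+1 positions O - s + 1 .. p + 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval, ValidationError


class BreakpointError(ValidationError):
    pass


def deletion_length(start: int, end: int) -> int:
    """Length in bp of a deletion spanning [start, end], 1-based inclusive."""
    if end < start:
        raise BreakpointError(f"end ({end}) < start ({start})")
    return end - start + 1


def microhomology_from_intervals(i1: GenomicInterval, i2: GenomicInterval) -> int:
    """Microhomology length from the two printed flank intervals.

    The 5' and 3' copies of the shared sequence occupy equal-length
    intervals; either one's inclusive length is the microhomology length.
    """
    if len(i1) != len(i2):
        raise BreakpointError(
            f"flank intervals differ in length: {len(i1)} vs {len(i2)}"
        )
    return len(i1)


@dataclass(frozen=True)
class DeletionCall:
    """A characterized deletion with its breakpoint ambiguity.

    ``five_prime_interval`` holds every possible deletion start position and
    ``three_prime_interval`` the corresponding end positions (the k-th start
    pairs with the k-th end); both have length ``microhomology_len + 1``.
    """

    contig: str
    five_prime_interval: GenomicInterval
    three_prime_interval: GenomicInterval
    deletion_length: int
    microhomology_seq: str
    microhomology_len: int

    def __post_init__(self) -> None:
        if len(self.five_prime_interval) != self.microhomology_len + 1:
            raise BreakpointError("5' interval length must equal mh + 1")
        if len(self.three_prime_interval) != self.microhomology_len + 1:
            raise BreakpointError("3' interval length must equal mh + 1")
        if len(self.microhomology_seq) != self.microhomology_len:
            raise BreakpointError("microhomology sequence/length mismatch")

    @property
    def placements(self) -> list[tuple[int, int]]:
        """All equivalent (start, end) breakpoint placements, 5'-most first."""
        f, t = self.five_prime_interval, self.three_prime_interval
        return [(f.start + k, t.start + k) for k in range(self.microhomology_len + 1)]

    @property
    def hgvs(self) -> str:
        return format_hgvs(self)


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat element (e.g. an Alu family member) at a genomic interval."""

    interval: GenomicInterval
    family: str


def _lcp_len(a: str, b: str) -> int:
    """Longest common prefix length; 'N' never matches (conservative under
    ambiguity)."""
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


_SEQ_RE = re.compile(r"^[ACGTN]*$")


def infer_deletion(
    reference: str,
    observed: str,
    contig: str = "ref",
    offset: int = 1,
) -> DeletionCall:
    """Characterize the single contiguous deletion turning ``reference`` into
    ``observed``.

    ``offset`` is the 1-based genomic position of the first reference base,
    so toy sub-references can report genome-scale coordinates. Raises
    :class:`BreakpointError` when the two sequences are not related by
    exactly one clean deletion (e.g. a substitution or an inserted junction
    sequence is present).
    """
    reference = reference.upper()
    observed = observed.upper()
    for label, seq in (("reference", reference), ("observed", observed)):
        if not _SEQ_RE.match(seq):
            raise BreakpointError(f"{label} contains non-ACGTN characters")
    if len(observed) >= len(reference):
        raise BreakpointError(
            "observed sequence is not shorter than the reference "
            f"({len(observed)} >= {len(reference)}): no deletion to infer"
        )
    p = _lcp_len(reference, observed)
    s = _lcp_len(reference[::-1], observed[::-1])
    O = len(observed)
    del_len = len(reference) - O
    if p + s < O:
        raise BreakpointError(
            "not a clean deletion: flanks mismatch beyond a single deleted "
            f"segment (LCP {p} + LCS {s} < observed length {O})"
        )
    mh = p + s - O
    leftmost = O - s + 1  # leftmost possible deletion start, 1-based in reference
    mh_seq = reference[leftmost - 1 : leftmost - 1 + mh]
    g = offset - 1  # shift to genomic coordinates
    return DeletionCall(
        contig=contig,
        five_prime_interval=GenomicInterval(contig, g + leftmost, g + leftmost + mh),
        three_prime_interval=GenomicInterval(
            contig, g + leftmost + del_len - 1, g + leftmost + del_len - 1 + mh
        ),
        deletion_length=del_len,
        microhomology_seq=mh_seq,
        microhomology_len=mh,
    )


# ---------------------------------------------------------------------------
# HGVS rendering

_HGVS_EXACT_RE = re.compile(r"^(?P<contig>[^:]+):g\.(?P<start>\d+)_(?P<end>\d+)del$")
_HGVS_AMBIG_RE = re.compile(
    r"^(?P<contig>[^:]+):g\."
    r"\((?P<a>\d+)_(?P<b>\d+)\)_\((?P<c>\d+)_(?P<d>\d+)\)del$"
)


def format_hgvs(call: DeletionCall, report_mode: str = "ambiguous") -> str:
    """Render a deletion call in HGVS g. notation.

    With zero microhomology the placement is unique and the exact form
    ``contig:g.start_enddel`` is produced. Otherwise ``report_mode``
    selects the ambiguous-interval form ``contig:g.(a_b)_(c_d)del`` (the
    default: the breakpoint genuinely cannot be placed within the
    homologous flanks) or ``"shifted"``, the 3'-most placement required by
    the HGVS shifting rule.
    """
    if call.microhomology_len == 0:
        start, end = call.placements[0]
        return f"{call.contig}:g.{start}_{end}del"
    if report_mode == "shifted":
        start, end = call.placements[-1]
        return f"{call.contig}:g.{start}_{end}del"
    if report_mode != "ambiguous":
        raise BreakpointError(f"unknown report_mode {report_mode!r}")
    f, t = call.five_prime_interval, call.three_prime_interval
    return f"{call.contig}:g.({f.start}_{f.end})_({t.start}_{t.end})del"


def parse_hgvs_deletion(
    text: str,
) -> tuple[str, GenomicInterval, GenomicInterval]:
    """Parse exact or ambiguous HGVS deletion notation back into the contig
    and the (5' starts, 3' ends) placement intervals."""
    m = _HGVS_AMBIG_RE.match(text.strip())
    if m:
        contig = m.group("contig")
        return (
            contig,
            GenomicInterval(contig, int(m.group("a")), int(m.group("b"))),
            GenomicInterval(contig, int(m.group("c")), int(m.group("d"))),
        )
    m = _HGVS_EXACT_RE.match(text.strip())
    if m:
        contig = m.group("contig")
        s, e = int(m.group("start")), int(m.group("end"))
        return contig, GenomicInterval(contig, s, s), GenomicInterval(contig, e, e)
    raise BreakpointError(f"cannot parse HGVS deletion {text!r}")


# ---------------------------------------------------------------------------
# flanking repeats


def annotate_flanking_repeats(
    call: DeletionCall,
    repeats: Sequence[RepeatAnnotation],
    window: int = 1000,
) -> list[tuple[RepeatAnnotation, str]]:
    """Repeats near the breakpoints, labeled 5'-side / 3'-side / internal.

    Considers repeats intersecting [5' interval start - window, 3' interval
    end + window] on the call's contig. A repeat ending at or before the
    last possible deletion start is 5'-side; one beginning at or after the
    first possible deletion end is 3'-side; anything else lies within the
    deleted segment. Alu-flanked deletions are the motivating case: short
    interspersed repeats at both sides mark likely recombination substrates.
    """
    lo = max(1, call.five_prime_interval.start - window)
    hi = call.three_prime_interval.end + window
    roi = GenomicInterval(call.contig, lo, hi)
    out: list[tuple[RepeatAnnotation, str]] = []
    for rep in sorted(repeats, key=lambda r: (r.interval.start, r.interval.end)):
        if rep.interval.contig != call.contig or not rep.interval.intersects(roi):
            continue
        if rep.interval.end <= call.five_prime_interval.end:
            side = "5'-side"
        elif rep.interval.start >= call.three_prime_interval.start:
            side = "3'-side"
        else:
            side = "internal"
        out.append((rep, side))
    return out


def read_repeat_bed(path: str) -> list[RepeatAnnotation]:
    """Read repeats from BED (0-based half-open; column 4 = family label)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise BreakpointError(f"{path}:{lineno}: expected >=4 columns")
            iv = GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2]))
            out.append(RepeatAnnotation(iv, parts[3]))
    return out


def majority_consensus(alignments, region) -> str:
    """Naive per-position majority consensus over aligned reads.

    A convenience for turning the simulator's breakpoint-spanning read sets
    into an observed sequence for :func:`infer_deletion`. Each reference
    position in ``region`` gets the most frequent aligned base (ties broken
    alphabetically, positions without coverage become ``N``); read
    insertions are ignored and read deletions simply cast no vote, so this
    is not a substitute for real consensus/assembly of complex events.
    """
    import pysam  # local import keeps module import light

    from .intervals import GenomicInterval  # noqa: F401  (type reference)

    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, check_sq=False) as af:
            reads = [r for r in af]
    else:
        reads = list(alignments)
    counts: list[dict[str, int]] = [dict() for _ in range(len(region))]
    lo0, hi0 = region.start - 1, region.end
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.reference_name != region.contig or read.query_sequence is None:
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if lo0 <= rpos < hi0:
                base = read.query_sequence[qpos]
                slot = counts[rpos - lo0]
                slot[base] = slot.get(base, 0) + 1
    out = []
    for slot in counts:
        if not slot:
            out.append("N")
        else:
            out.append(max(sorted(slot), key=lambda b: slot[b]))
    return "".join(out)


def call_to_vcf(call: DeletionCall) -> str:
    """Render a call as a minimal symbolic-deletion VCF document.

    POS anchors on the base before the leftmost placement; CIPOS/CIEND carry
    the breakpoint ambiguity (0..microhomology_len on both ends), so a
    microhomology-free call has zero-width confidence intervals.
    """
    mh = call.microhomology_len
    start, end = call.placements[0]
    pos = max(1, start - 1)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={call.contig}>",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Deletion end">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Start ambiguity">',
        '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="End ambiguity">',
        '##INFO=<ID=MHLEN,Number=1,Type=Integer,Description="Microhomology length">',
        '##INFO=<ID=MHSEQ,Number=1,Type=String,Description="Microhomology sequence">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    info = (
        f"SVTYPE=DEL;END={end};SVLEN={-call.deletion_length};"
        f"CIPOS=0,{mh};CIEND=0,{mh};MHLEN={mh}"
        + (f";MHSEQ={call.microhomology_seq}" if mh else "")
    )
    lines.append(f"{call.contig}\t{pos}\t.\tN\t<DEL>\t.\tPASS\t{info}")
    return "\n".join(lines) + "\n"


def call_to_tsv_row(call: DeletionCall) -> str:
    """One-line TSV rendering of a call (columns: contig, 5' interval,
    3' interval, length, mh_len, mh_seq, hgvs)."""
    f, t = call.five_prime_interval, call.three_prime_interval
    return "\t".join(
        [
            call.contig,
            f"{f.start}-{f.end}",
            f"{t.start}-{t.end}",
            str(call.deletion_length),
            str(call.microhomology_len),
            call.microhomology_seq or ".",
            call.hgvs,
        ]
    )
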