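"""1-based inclusive genomic intervals and the interval algebra used panel-wide.

Every coordinate in this package is 1-based and inclusive, matching HGVS g.
notation: an interval ``(contig, start, end)`` contains ``end - start + 1``
bases. BED input/output converts at the boundary (see :mod:`lramp.panel`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval ``[start, end]`` on ``contig``, 1-based."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) < start ({self.start}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def intersects(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.intersects(other):
            return None
        return GenomicInterval(
            self.contig, max(self.start, other.start), min(self.end, other.end)
        )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


_REGION_RE = re.compile(r"^(?P<contig>[^:]+):(?P<start>[\d,]+)[-_](?P<end>[\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``contig:start-end`` (1-based inclusive) into an interval."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValidationError(f"cannot parse region string {text!r}")
    return GenomicInterval(
        m.group("contig"),
        int(m.group("start").replace(",", "")),
        int(m.group("end").replace(",", "")),
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal disjoint intervals.

    Abutting intervals (end + 1 == next start) are merged: the union of
    [1,100] and [101,200] is [1,200].
    """
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_start, cur_end))
    return out


def union_size(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of bases covered by at least one interval."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def complement_within(
    target: GenomicInterval, intervals: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal sub-intervals of ``target`` covered by none of ``intervals``."""
    covered = [
        iv
        for iv in merge_intervals(
            i for i in intervals if i.intersects(target)
        )
    ]
    gaps: list[GenomicInterval] = []
    cursor = target.start
    for iv in covered:
        lo, hi = max(iv.start, target.start), min(iv.end, target.end)
        if lo > cursor:
            gaps.append(GenomicInterval(target.contig, cursor, lo - 1))
        cursor = max(cursor, hi + 1)
    if cursor <= target.end:
        gaps.append(GenomicInterval(target.contig, cursor, target.end))
    return gaps


def depth_at_least(
    intervals: Sequence[GenomicInterval], min_depth: int
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least ``min_depth`` of ``intervals``.

    Sweep-line over interval endpoints; used for amplicon-overlap detection
    (``min_depth=2``).
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        # +1 at start, -1 just past end (half-open on the event line)
        by_contig.setdefault(iv.contig, []).append((iv.start, +1))
        by_contig[iv.contig].append((iv.end + 1, -1))
    out: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        events = sorted(by_contig[contig])
        depth = 0
        run_start: int | None = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth >= min_depth and run_start is None:
                run_start = pos
            elif depth < min_depth and run_start is not None:
                out.append(GenomicInterval(contig, run_start, pos - 1))
                run_start = None
    return out
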