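"""Bundled example data: the 35-locus inherited-retinal-disease (IRD) panel
and the macular-dystrophy cohort tallies, plus diagnostic-yield arithmetic.

The panel ships as published per-locus genomic target sizes (the number of
LR PCRs and the total bases each locus' amplicon union covers). Exact
amplicon coordinates are not part of the published design, so each locus is
represented as a single interval of the published size laid out on its own
contig; panel-level accounting (locus/total target size) is exact under
this representation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval
from .panel import Amplicon, AmpliconPanel, Locus

# locus -> (number of LR PCRs, genomic target size in bp)
IRD_PANEL_TABLE: dict[str, tuple[int, int]] = {
    "PPT1": (2, 26_746),
    "ABCA4": (8, 137_748),
    "CRB1": (14, 212_898),
    "PCARE": (1, 18_628),
    "EFEMP1": (5, 60_569),
    "IMPG2": (6, 94_768),
    "PROM1": (7, 117_712),
    "MFSD8": (3, 49_747),
    "CTNNA1": (13, 182_694),
    "GUCA1A": (2, 27_191),
    "GUCA1B": (1, 13_548),
    "PRPH2": (2, 32_242),
    "IMPG1": (11, 144_700),
    "ELOVL4": (2, 34_792),
    "DHS6S1": (1, 13_473),
    "RP1L1": (3, 51_877),
    "RP1": (1, 16_930),
    "CNGB3": (12, 172_052),
    "KCNV2": (1, 15_214),
    "ATOH7": (1, 9_275),
    "PDE6C": (3, 53_794),
    "BEST1": (1, 17_272),
    "C1QTNF5": (1, 10_536),
    "PDE6H": (1, 11_084),
    "RDH5": (1, 6_122),
    "OTX2": (1, 12_758),
    "NR2E3": (1, 11_097),
    "RLBP1": (1, 13_667),
    "GUCY2D": (1, 18_939),
    "FSCN2": (1, 11_574),
    "RAX2": (1, 5_845),
    "TIMP3": (5, 67_146),
    "RS1": (3, 34_731),
    "RPGR": (4, 60_808),
    "RP2": (3, 46_521),
}


def ird_panel() -> AmpliconPanel:
    """The 35-locus IRD panel as an :class:`AmpliconPanel`.

    One single-interval locus per published entry, each on its own contig
    named after the locus, spanning ``[1, target_size]``.
    """
    loci = []
    for name, (_n_pcrs, size) in IRD_PANEL_TABLE.items():
        iv = GenomicInterval(name, 1, size)
        loci.append(Locus(name, (Amplicon(f"{name}_A1", iv),), target=iv))
    return AmpliconPanel(loci=loci)


def ird_pcr_count() -> int:
    """Total number of validated LR PCRs across the panel."""
    return sum(n for n, _size in IRD_PANEL_TABLE.values())


# ---------------------------------------------------------------------------
# cohort tallies and yield arithmetic

# diagnosed / total per published cohort stratum
COHORT_COUNTS: dict[str, tuple[int, int]] = {
    "first_tier_no_previous_testing": (48, 94),
    "first_tier_plus_wes_undiagnosed": (31, 94),
    "md_overall": (132, 168),
    "stgd": (84, 95),
}


@dataclass(frozen=True)
class YieldResult:
    label: str
    count: int
    total: int
    percent: float


def diagnostic_yield(count: int, total: int, label: str = "") -> YieldResult:
    """Percentage yield from raw counts, rounded to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return YieldResult(label, count, total, round(100.0 * count / total, 1))


def cohort_yields() -> dict[str, YieldResult]:
    """Diagnostic-yield percentages for the bundled cohort tallies."""
    return {
        label: diagnostic_yield(c, t, label)
        for label, (c, t) in COHORT_COUNTS.items()
    }
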