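"""Read-backed cis/trans phasing of candidate compound-heterozygous variants.

Two pathogenic variants cause recessive disease only when they sit on
opposite haplotypes (in trans). When relatives are unavailable for
segregation analysis, sequencing fragments (read pairs) that co-observe
heterozygous sites can settle the question: a fragment carrying both ALT
alleles (or both REF) of a site pair is cis evidence, one of each is trans
evidence, and evidence chains transitively through intervening informative
heterozygous sites. The relative phase of two sites connected by a chain is
the parity (XOR) of the edge calls along it.

The graph is deliberately conservative: edges must clear support and
conflict-fraction thresholds, and any parity-inconsistent cycle in the
connected component makes the pair unresolved rather than majority-voted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pysam

from .intervals import GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_SUPPORT = 2
DEFAULT_MAX_CONFLICT_FRACTION = 0.2


class Allele(Enum):
    REF = 0
    ALT = 1
    MISSING = 2


class Phase(Enum):
    CIS = "cis"
    TRANS = "trans"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class HetSite:
    """One heterozygous site usable as a phasing marker."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_id: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"site {self.contig}:{self.pos}: alleles identical")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class FragmentObservation:
    """Alleles one fragment (merged read pair) observed at phasing sites."""

    fragment_id: str
    alleles: dict[int, Allele]
    min_base_quality: int = DEFAULT_MIN_BASEQ
    min_mapping_quality: int = DEFAULT_MIN_MAPQ

    @property
    def informative_sites(self) -> list[int]:
        return sorted(
            sid for sid, a in self.alleles.items() if a is not Allele.MISSING
        )

    @property
    def is_informative(self) -> bool:
        return len(self.informative_sites) >= 2


# ---------------------------------------------------------------------------
# site extraction


def _is_het(gt: tuple) -> bool:
    alleles = [a for a in gt if a is not None]
    return len(alleles) == 2 and alleles[0] != alleles[1]


def extract_informative_sites(
    vcf_path: str,
    region: GenomicInterval,
    sample: str | None = None,
    candidates: Sequence[tuple[str, int, str, str]] = (),
) -> list[HetSite]:
    """Heterozygous sites within ``region`` from a genotyped VCF.

    Multiallelic records are decomposed per ALT allele; only REF/ALT
    heterozygous genotypes become sites (het-alt genotypes such as 1/2 are
    skipped with a log message, since the REF/ALT observation model does
    not apply). ``candidates`` are (contig, pos, ref, alt) tuples that
    *must* come out heterozygous - the phasing question is ill-posed
    otherwise - and an error is raised if any is not.
    """
    sites: list[HetSite] = []
    wanted = {(c, p, r, a) for c, p, r, a in candidates}
    seen: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(vcf_path) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise ValidationError(f"{vcf_path} carries no genotype columns")
        use = sample or sample_names[0]
        for rec in vcf:
            if rec.contig != region.contig or rec.pos < region.start or rec.pos > region.end:
                continue
            gt = rec.samples[use].get("GT")
            if gt is None or not _is_het(gt):
                continue
            nonref = [a for a in gt if a not in (None, 0)]
            if len(set(nonref)) > 1:
                logger.info(
                    "skipping het-alt genotype at %s:%d (no REF allele)",
                    rec.contig, rec.pos,
                )
                continue
            if not nonref:  # 0/0 can't be het; guarded by _is_het
                continue
            alt = rec.alleles[nonref[0]]
            key = (rec.contig, rec.pos, rec.ref, alt)
            seen.add(key)
            sites.append(HetSite(rec.contig, rec.pos, rec.ref, alt, site_id=-1))
    missing = wanted - seen
    if missing:
        raise ValidationError(
            "candidate variant(s) not heterozygous in VCF: "
            + ", ".join(f"{c}:{p}:{r}>{a}" for c, p, r, a in sorted(missing))
        )
    sites.sort(key=lambda s: s.pos)
    return [
        HetSite(s.contig, s.pos, s.ref_allele, s.alt_allele, site_id=i)
        for i, s in enumerate(sites)
    ]


# ---------------------------------------------------------------------------
# fragment observations


def _read_allele_at(
    read: pysam.AlignedSegment, site: HetSite, min_baseq: int
) -> Allele:
    """Allele a single read shows at a site, resolved from alignment ops.

    SNVs compare the aligned base; indel alleles are matched by the
    presence/absence of the corresponding insertion/deletion in the
    alignment immediately at the site (left-aligned indels assumed
    upstream). Low-quality bases and partial spans yield MISSING.
    """
    ref0 = site.pos - 1  # 0-based
    quals = read.query_qualities
    seq = read.query_sequence
    if seq is None:
        return Allele.MISSING
    pairs = read.get_aligned_pairs()
    ref_to_q: dict[int, int | None] = {}
    inserted_after: dict[int, list[int]] = {}
    last_ref = None
    for qpos, rpos in pairs:
        if rpos is not None:
            ref_to_q[rpos] = qpos
            last_ref = rpos
        elif qpos is not None and last_ref is not None:
            inserted_after.setdefault(last_ref, []).append(qpos)

    def base_ok(qpos: int | None) -> bool:
        return qpos is not None and (quals is None or quals[qpos] >= min_baseq)

    ref_len, alt_len = len(site.ref_allele), len(site.alt_allele)

    if site.is_snv:
        qpos = ref_to_q.get(ref0)
        if qpos is None or not base_ok(qpos):
            return Allele.MISSING
        base = seq[qpos]
        if base == site.alt_allele:
            return Allele.ALT
        if base == site.ref_allele:
            return Allele.REF
        return Allele.MISSING

    # indel site: require the read to span one base beyond the ref allele
    span_end = ref0 + ref_len  # first ref base after the allele
    if not (read.reference_start <= ref0 and read.reference_end is not None
            and read.reference_end > span_end):
        return Allele.MISSING

    if ref_len > alt_len and site.ref_allele.startswith(site.alt_allele):
        # deletion variant: anchor base kept, following bases deleted
        deleted = range(ref0 + alt_len, ref0 + ref_len)
        anchor_q = ref_to_q.get(ref0)
        if not base_ok(anchor_q):
            return Allele.MISSING
        qs = [ref_to_q.get(r) for r in deleted]
        if all(q is None for q in qs):
            return Allele.ALT
        if all(base_ok(q) for q in qs) and all(
            seq[q] == site.ref_allele[i + alt_len]  # type: ignore[index]
            for i, q in enumerate(qs)
        ) and not inserted_after.get(ref0):
            return Allele.REF
        return Allele.MISSING

    if alt_len > ref_len and site.alt_allele.startswith(site.ref_allele):
        # insertion variant: extra bases appear after the anchor
        anchor_ref = ref0 + ref_len - 1
        anchor_q = ref_to_q.get(anchor_ref)
        if not base_ok(anchor_q):
            return Allele.MISSING
        ins_q = inserted_after.get(anchor_ref, [])
        ins_seq = "".join(seq[q] for q in ins_q)
        expected = site.alt_allele[ref_len:]
        if ins_seq == expected and all(base_ok(q) for q in ins_q):
            return Allele.ALT
        if not ins_q:
            return Allele.REF
        return Allele.MISSING

    # complex allele (e.g. MNV / delins): compare the aligned query sequence
    qs = [ref_to_q.get(r) for r in range(ref0, ref0 + ref_len)]
    if all(base_ok(q) for q in qs):
        obs = "".join(seq[q] for q in qs)  # type: ignore[index]
        if obs == site.ref_allele and not any(
            inserted_after.get(r) for r in range(ref0, ref0 + ref_len - 1)
        ):
            return Allele.REF
    return Allele.MISSING


def collect_fragment_observations(
    alignments: str | Iterable[pysam.AlignedSegment],
    sites: Sequence[HetSite],
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[FragmentObservation]:
    """Per-fragment allele observations at the phasing sites.

    Both mates of a pair are merged by read name into one fragment;
    contradictory mate calls at a site blank that site to MISSING (and are
    logged). Secondary and supplementary alignments are ignored. Fragments
    observing fewer than two sites are dropped as uninformative.
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, check_sq=False) as af:
            reads = [r for r in af]
    else:
        reads = list(alignments)
    by_site_contig: dict[str, list[HetSite]] = {}
    for s in sites:
        by_site_contig.setdefault(s.contig, []).append(s)

    frags: dict[str, dict[int, Allele]] = {}
    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.mapping_quality < min_mapq
        ):
            continue
        contig_sites = by_site_contig.get(read.reference_name or "", [])
        if not contig_sites:
            continue
        start1 = read.reference_start + 1
        end1 = read.reference_end or read.reference_start
        alleles = frags.setdefault(read.query_name, {})
        for site in contig_sites:
            if not (start1 <= site.pos <= end1):
                continue
            call = _read_allele_at(read, site, min_baseq)
            if call is Allele.MISSING:
                alleles.setdefault(site.site_id, Allele.MISSING)
                continue
            prev = alleles.get(site.site_id)
            if prev in (None, Allele.MISSING):
                alleles[site.site_id] = call
            elif prev is not call:
                logger.info(
                    "fragment %s: mates disagree at site %s; set to MISSING",
                    read.query_name, site,
                )
                alleles[site.site_id] = Allele.MISSING

    out = []
    for name, alleles in sorted(frags.items()):
        obs = FragmentObservation(name, alleles, min_baseq, min_mapq)
        if obs.is_informative:
            out.append(obs)
    return out


# ---------------------------------------------------------------------------
# phase graph


@dataclass(frozen=True)
class PhaseEdge:
    site_i: int
    site_j: int
    parity: Phase  # CIS or TRANS (majority call)
    support_count: int
    conflict_count: int

    @property
    def conflict_fraction(self) -> float:
        total = self.support_count + self.conflict_count
        return self.conflict_count / total if total else 0.0


@dataclass
class PhaseGraph:
    """Parity graph over heterozygous sites built from fragment evidence."""

    sites: dict[int, HetSite]
    edges: list[PhaseEdge] = field(default_factory=list)

    def to_networkx(
        self,
        min_support: int = 1,
        max_conflict_fraction: float = 1.0,
    ) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.sites)
        for e in self.edges:
            if e.support_count < min_support:
                continue
            if e.conflict_fraction > max_conflict_fraction:
                continue
            g.add_edge(e.site_i, e.site_j, edge=e)
        return g


def build_phase_graph(
    observations: Sequence[FragmentObservation],
    sites: Sequence[HetSite] | Mapping[int, HetSite] = (),
) -> PhaseGraph:
    """Tally cis/trans evidence for every co-observed site pair.

    A fragment showing equal alleles at two sites (ALT,ALT or REF,REF) is
    one cis observation for that pair; unequal alleles are one trans
    observation. REF,REF counts as cis because both sites are heterozygous:
    a fragment with both REF alleles is the other haplotype intact. The
    retained edge carries the majority parity with its support and conflict
    counts; a tied tally is kept (parity = cis by convention) but its 0.5
    conflict fraction fails any sensible threshold downstream.
    """
    tallies: dict[tuple[int, int], dict[Phase, int]] = {}
    site_map: dict[int, HetSite]
    if isinstance(sites, Mapping):
        site_map = dict(sites)
    else:
        site_map = {s.site_id: s for s in sites}
    for obs in observations:
        informative = obs.informative_sites
        for i, j in combinations(informative, 2):
            parity = (
                Phase.CIS if obs.alleles[i] is obs.alleles[j] else Phase.TRANS
            )
            tallies.setdefault((i, j), {Phase.CIS: 0, Phase.TRANS: 0})[parity] += 1
    edges = []
    for (i, j), tally in sorted(tallies.items()):
        cis, trans = tally[Phase.CIS], tally[Phase.TRANS]
        parity = Phase.CIS if cis >= trans else Phase.TRANS
        edges.append(
            PhaseEdge(i, j, parity, max(cis, trans), min(cis, trans))
        )
    return PhaseGraph(sites=site_map, edges=edges)


@dataclass
class PhaseCall:
    """Result of phasing one site pair through the graph."""

    site_a: int
    site_b: int
    call: Phase
    path: list[PhaseEdge] = field(default_factory=list)
    support: int = 0
    conflicts: int = 0
    reason: str = ""

    def __str__(self) -> str:
        via = " -> ".join(f"({e.site_i},{e.site_j},{e.parity.value})" for e in self.path)
        return (
            f"phase({self.site_a},{self.site_b}) = {self.call.value}"
            + (f" via {via}" if via else "")
            + (f" [{self.reason}]" if self.reason else "")
        )


def phase_pair(
    graph: PhaseGraph,
    a: int | HetSite,
    b: int | HetSite,
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_conflict_fraction: float = DEFAULT_MAX_CONFLICT_FRACTION,
) -> PhaseCall:
    """Relative phase of sites ``a`` and ``b`` through reliable evidence.

    Edges failing the support or conflict thresholds are excluded; the call
    is the XOR of edge parities along a connecting path (trans = 1). If the
    two sites are not connected by reliable edges, or the connected
    component containing them has any parity-inconsistent cycle (i.e.
    different paths would disagree), the pair is UNRESOLVED with a
    diagnostic - a diagnostic tool must not overcall.
    """
    aid = a.site_id if isinstance(a, HetSite) else a
    bid = b.site_id if isinstance(b, HetSite) else b
    if aid == bid:
        logger.warning("phase_pair called with identical sites (%d)", aid)
        return PhaseCall(aid, bid, Phase.CIS, reason="degenerate: same site")
    g = graph.to_networkx(min_support, max_conflict_fraction)
    if aid not in g or bid not in g:
        return PhaseCall(aid, bid, Phase.UNRESOLVED, reason="site not in graph")
    if not nx.has_path(g, aid, bid):
        return PhaseCall(
            aid, bid, Phase.UNRESOLVED,
            reason="no chain of reliable evidence connects the sites",
        )
    # parity labeling by BFS; any edge contradicting its endpoints' labels
    # is a parity-inconsistent cycle in the component
    component = nx.node_connected_component(g, aid)
    label = {aid: 0}
    for u, v in nx.bfs_edges(g, aid):
        if v in component and v not in label:
            e: PhaseEdge = g.edges[u, v]["edge"]
            label[v] = label[u] ^ (1 if e.parity is Phase.TRANS else 0)
    for u, v, data in g.edges(data=True):
        if u in label and v in label:
            e = data["edge"]
            want = 1 if e.parity is Phase.TRANS else 0
            if (label[u] ^ label[v]) != want:
                return PhaseCall(
                    aid, bid, Phase.UNRESOLVED,
                    reason=(
                        "conflicting evidence paths: edge "
                        f"({u},{v}) disagrees with the chain parity"
                    ),
                )
    path_nodes = nx.shortest_path(g, aid, bid)
    path_edges = [
        g.edges[u, v]["edge"] for u, v in zip(path_nodes, path_nodes[1:])
    ]
    call = Phase.TRANS if (label[aid] ^ label[bid]) else Phase.CIS
    return PhaseCall(
        aid,
        bid,
        call,
        path=path_edges,
        support=min(e.support_count for e in path_edges),
        conflicts=sum(e.conflict_count for e in path_edges),
    )


def phase_report_rows(
    graph: PhaseGraph, calls: Sequence[PhaseCall]
) -> Iterable[str]:
    """TSV rows (site_a, site_b, call, path, min_support, conflicts)."""
    yield "site_a\tsite_b\tcall\tpath\tmin_support\tconflicts"
    for c in calls:
        sa = graph.sites.get(c.site_a)
        sb = graph.sites.get(c.site_b)
        path = ";".join(
            f"{e.site_i}-{e.site_j}:{e.parity.value}" for e in c.path
        ) or "."
        yield (
            f"{sa if sa else c.site_a}\t{sb if sb else c.site_b}\t"
            f"{c.call.value}\t{path}\t{c.support}\t{c.conflicts}"
        )
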