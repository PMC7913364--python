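"""Phase-graph construction, parity algebra, and the MEC-oracle property."""

import numpy as np
import pytest

from lramp.intervals import GenomicInterval, ValidationError
from lramp.phasing import (
    Allele,
    FragmentObservation,
    HetSite,
    Phase,
    build_phase_graph,
    collect_fragment_observations,
    extract_informative_sites,
    phase_pair,
)
from lramp.simulate import (
    SimulationScenario,
    make_reference,
    simulate_fragments,
    write_truth_vcf,
)

from oracles import mec_relative_phase

R, A, M = Allele.REF, Allele.ALT, Allele.MISSING


def obs(fid, alleles):
    return FragmentObservation(fid, alleles)


def sites_for(n):
    return [HetSite("c", 100 * (i + 1), "A", "T", site_id=i) for i in range(n)]


class TestGraphBuilding:
    def test_transitive_chain_scenario(self):
        """One fragment joins sites 1-2 in cis; two fragments join 2-3 in
        trans (each carries exactly one of the two ALTs)."""
        graph = build_phase_graph(
            [obs("f1", {0: A, 1: A}), obs("f2", {1: A, 2: R}), obs("f3", {1: R, 2: A})],
            sites_for(3),
        )
        edges = {(e.site_i, e.site_j): e for e in graph.edges}
        assert edges[(0, 1)].parity is Phase.CIS
        assert edges[(0, 1)].support_count == 1
        assert edges[(1, 2)].parity is Phase.TRANS
        assert edges[(1, 2)].support_count == 2
        assert edges[(1, 2)].conflict_count == 0

    def test_single_trans_fragment(self):
        graph = build_phase_graph([obs("f", {0: A, 1: R})], sites_for(2))
        (e,) = graph.edges
        assert (e.parity, e.support_count, e.conflict_count) == (Phase.TRANS, 1, 0)

    def test_ref_ref_counts_as_cis(self):
        graph = build_phase_graph([obs("f", {0: R, 1: R})], sites_for(2))
        assert graph.edges[0].parity is Phase.CIS

    def test_disagreeing_fragments_tallied(self):
        graph = build_phase_graph(
            [obs("f1", {0: A, 1: A}), obs("f2", {0: A, 1: A}), obs("f3", {0: A, 1: R})],
            sites_for(2),
        )
        (e,) = graph.edges
        assert (e.support_count, e.conflict_count) == (2, 1)
        assert e.conflict_fraction == pytest.approx(1 / 3)

    def test_uninformative_fragment_ignored(self):
        base = [obs("f1", {0: A, 1: A}), obs("f2", {1: A, 2: R})]
        extra = base + [obs("f3", {0: A, 1: M, 2: M})]
        g1 = build_phase_graph(base, sites_for(3))
        g2 = build_phase_graph(
            [o for o in extra if o.is_informative], sites_for(3)
        )
        assert g1.edges == g2.edges


class TestPhasePair:
    def test_cis_plus_trans_chain_gives_trans(self):
        graph = build_phase_graph(
            [obs(f"c{i}", {0: A, 1: A}) for i in range(2)]
            + [obs(f"t{i}", {1: A, 2: R}) for i in range(2)],
            sites_for(3),
        )
        call = phase_pair(graph, 0, 2)
        assert call.call is Phase.TRANS
        assert call.support == 2
        assert call.conflicts == 0

    def test_two_trans_edges_give_cis(self):
        graph = build_phase_graph(
            [obs(f"a{i}", {0: A, 1: R}) for i in range(2)]
            + [obs(f"b{i}", {1: R, 2: A}) for i in range(2)],
            sites_for(3),
        )
        assert phase_pair(graph, 0, 2).call is Phase.CIS

    def test_symmetry(self):
        graph = build_phase_graph(
            [obs(f"f{i}", {0: A, 1: R}) for i in range(3)], sites_for(2)
        )
        assert phase_pair(graph, 0, 1).call is phase_pair(graph, 1, 0).call

    def test_same_site_degenerate_cis(self):
        graph = build_phase_graph([obs("f", {0: A, 1: A})], sites_for(2))
        assert phase_pair(graph, 0, 0).call is Phase.CIS

    def test_low_support_unresolved(self):
        graph = build_phase_graph([obs("f", {0: A, 1: R})], sites_for(2))
        call = phase_pair(graph, 0, 1, min_support=2)
        assert call.call is Phase.UNRESOLVED

    def test_conflicted_edge_unresolved(self):
        frags = [obs(f"f{i}", {0: A, 1: A}) for i in range(3)] + [
            obs(f"g{i}", {0: A, 1: R}) for i in range(2)
        ]
        graph = build_phase_graph(frags, sites_for(2))
        call = phase_pair(graph, 0, 1, min_support=2, max_conflict_fraction=0.2)
        assert call.call is Phase.UNRESOLVED

    def test_disconnected_unresolved(self):
        graph = build_phase_graph(
            [obs("f", {0: A, 1: A}), obs("g", {2: A, 3: A})], sites_for(4)
        )
        call = phase_pair(graph, 0, 3, min_support=1)
        assert call.call is Phase.UNRESOLVED
        assert "no chain" in call.reason

    def test_inconsistent_cycle_unresolved(self):
        # triangle whose parities cannot be 2-colored: cis+cis+trans
        frags = (
            [obs(f"a{i}", {0: A, 1: A}) for i in range(2)]
            + [obs(f"b{i}", {1: A, 2: A}) for i in range(2)]
            + [obs(f"c{i}", {0: A, 2: R}) for i in range(2)]
        )
        graph = build_phase_graph(frags, sites_for(3))
        call = phase_pair(graph, 0, 2, min_support=1, max_conflict_fraction=0.0)
        assert call.call is Phase.UNRESOLVED
        assert "disagrees" in call.reason or "conflicting" in call.reason

    def test_path_parity_is_path_independent_on_consistent_graphs(self):
        """Random conflict-free graphs: every reliable path between two sites
        yields the same parity, so the call never depends on path choice."""
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            truth = rng.integers(0, 2, size=n)  # haplotype side per site
            frags = []
            for k in range(25):
                pair = sorted(rng.choice(n, size=2, replace=False))
                i, j = int(pair[0]), int(pair[1])
                hap = int(rng.integers(2))
                def allele(s):
                    return A if truth[s] == hap else R
                frags.append(obs(f"f{k}", {i: allele(i), j: allele(j)}))
            graph = build_phase_graph(frags, sites_for(n))
            for a in range(n):
                for b in range(a + 1, n):
                    call = phase_pair(graph, a, b, min_support=1)
                    if call.call is Phase.UNRESOLVED:
                        continue
                    expect = Phase.CIS if truth[a] == truth[b] else Phase.TRANS
                    assert call.call is expect


class TestMecOracle:
    def _random_instance(self, rng):
        n = int(rng.integers(2, 11))
        truth = rng.integers(0, 2, size=n)
        n_frags = int(rng.integers(2, 31))
        err = float(rng.choice([0.0, 0.0, 0.05]))
        frags = []
        for k in range(n_frags):
            size = int(rng.integers(2, min(n, 4) + 1))
            cover = sorted(rng.choice(n, size=size, replace=False).tolist())
            hap = int(rng.integers(2))
            alleles = {}
            for s in cover:
                bit = truth[s] == hap
                if rng.random() < err:
                    bit = not bit
                alleles[s] = A if bit else R
            frags.append(obs(f"f{k}", alleles))
        return n, truth, frags

    def test_confident_calls_agree_with_mec(self):
        """Whenever the parity graph produces a confident cis/trans call, the
        exhaustive minimum-error-correction bipartition yields the same
        relative phase (when the MEC optimum is unique)."""
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(300):
            n, _truth, frags = self._random_instance(rng)
            graph = build_phase_graph(frags, sites_for(n))
            raw = [
                {s: (1 if al is A else 0)
                 for s, al in f.alleles.items() if al is not M}
                for f in frags
            ]
            for a in range(n):
                for b in range(a + 1, n):
                    call = phase_pair(graph, a, b, min_support=1,
                                      max_conflict_fraction=0.0)
                    if call.call is Phase.UNRESOLVED:
                        continue
                    oracle = mec_relative_phase(raw, n, a, b)
                    if oracle is None:
                        continue
                    assert call.call.value == oracle, (n, a, b)
                    checked += 1
        assert checked > 500  # the comparison actually exercised many pairs

    def test_clean_data_resolves_all_connected_pairs_correctly(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 8))
            truth = rng.integers(0, 2, size=n)
            frags = []
            for k in range(40):
                i = int(rng.integers(0, n - 1)) if n > 1 else 0
                j = i + 1
                hap = int(rng.integers(2))
                frags.append(obs(f"f{k}", {
                    i: A if truth[i] == hap else R,
                    j: A if truth[j] == hap else R,
                }))
            graph = build_phase_graph(frags, sites_for(n))
            for a in range(n):
                for b in range(a + 1, n):
                    call = phase_pair(graph, a, b, min_support=1)
                    expect = Phase.CIS if truth[a] == truth[b] else Phase.TRANS
                    assert call.call is expect


class TestFromAlignments:
    """Site extraction from VCF and fragment collection from SAM records."""

    @pytest.fixture()
    def snv_scene(self, tmp_path):
        ref = make_reference(2_500, 21)
        # sites must sit within one 375 bp fragment span of each other;
        # hap0 carries ALTs at 600 and 950, hap1 at 780 (600-780 trans)
        def snv(pos):
            base = ref[pos - 1]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
            return (pos, base, alt)
        h0 = [snv(600), snv(950)]
        h1 = [snv(780)]
        fs = simulate_fragments(
            ref, (h0, h1), SimulationScenario(seed=3, depth=40), contig="sim"
        )
        sam = tmp_path / "r.sam"
        vcf = tmp_path / "v.vcf"
        fs.write_sam(str(sam))
        write_truth_vcf(str(vcf), "sim", ref, (h0, h1))
        return ref, h0, h1, str(sam), str(vcf)

    def test_extract_het_sites(self, snv_scene):
        _ref, h0, h1, _sam, vcf = snv_scene
        sites = extract_informative_sites(vcf, GenomicInterval("sim", 1, 2_500))
        assert [s.pos for s in sites] == [600, 780, 950]
        assert [s.site_id for s in sites] == [0, 1, 2]

    def test_hom_and_outside_records_excluded(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
            "c\t20\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\n"
            "c\t30\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
            "c\t40\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\n"
            "c\t50\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
            "c\t999\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        sites = extract_informative_sites(str(vcf), GenomicInterval("c", 1, 100))
        assert [s.pos for s in sites] == [10, 30, 50]

    def test_candidate_not_het_raises(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\n"
        )
        with pytest.raises(ValidationError, match="not heterozygous"):
            extract_informative_sites(
                str(vcf), GenomicInterval("c", 1, 100),
                candidates=[("c", 10, "A", "T")],
            )

    def test_fragments_collect_mate_pairs(self, snv_scene):
        _ref, _h0, _h1, sam, vcf = snv_scene
        sites = extract_informative_sites(vcf, GenomicInterval("sim", 1, 2_500))
        observations = collect_fragment_observations(sam, sites)
        assert observations, "no informative fragments collected"
        # every fragment merges both mates: ids unique
        ids = [o.fragment_id for o in observations]
        assert len(ids) == len(set(ids))
        graph = build_phase_graph(observations, sites)
        call = phase_pair(graph, sites[0], sites[1])
        assert call.call is Phase.TRANS  # opposite haplotypes
        call2 = phase_pair(graph, sites[0], sites[2])
        assert call2.call is Phase.CIS   # same haplotype

    def test_fragment_covering_single_site_dropped(self, snv_scene):
        _ref, _h0, _h1, sam, vcf = snv_scene
        sites = extract_informative_sites(vcf, GenomicInterval("sim", 1, 2_500))
        observations = collect_fragment_observations(sam, [sites[0], sites[2]])
        for o in observations:
            assert len(o.informative_sites) >= 2
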