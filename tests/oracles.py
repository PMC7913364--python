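"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes the dumbest correct route (per-base boolean
scans, exhaustive removal-and-compare, exhaustive haplotype bipartition)
and shares no code with the algorithms it checks.
"""

from __future__ import annotations

import numpy as np

from lramp.intervals import GenomicInterval


def per_base_union_size(intervals: list[GenomicInterval]) -> int:
    """Union size by marking every covered base in a boolean array."""
    total = 0
    for contig in {iv.contig for iv in intervals}:
        ivs = [iv for iv in intervals if iv.contig == contig]
        hi = max(iv.end for iv in ivs)
        mask = np.zeros(hi + 1, dtype=bool)
        for iv in ivs:
            mask[iv.start : iv.end + 1] = True
        total += int(mask.sum())
    return total


def per_base_regions(
    contig: str,
    intervals: list[GenomicInterval],
    lo: int,
    hi: int,
    min_depth: int,
    invert: bool = False,
) -> list[tuple[int, int]]:
    """Maximal runs in [lo, hi] where per-base depth >= min_depth (or, with
    ``invert``, < min_depth), via explicit per-base counting."""
    depth = np.zeros(hi + 2, dtype=int)
    for iv in intervals:
        if iv.contig != contig:
            continue
        a, b = max(iv.start, lo), min(iv.end, hi)
        if a <= b:
            depth[a : b + 1] += 1
    flag = depth[lo : hi + 1] < min_depth if invert else depth[lo : hi + 1] >= min_depth
    runs: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flag):
        if f and start is None:
            start = lo + i
        elif not f and start is not None:
            runs.append((start, lo + i - 1))
            start = None
    if start is not None:
        runs.append((start, hi))
    return runs


def exhaustive_deletion_placements(reference: str, observed: str) -> list[int]:
    """All 1-based start positions k such that removing
    ``reference[k .. k+D-1]`` yields ``observed`` exactly, found by literally
    trying every k."""
    D = len(reference) - len(observed)
    assert D > 0
    out = []
    for k0 in range(len(observed) + 1):
        if reference[:k0] + reference[k0 + D :] == observed:
            out.append(k0 + 1)
    return out


def mec_optimal_haplotypes(
    fragments: list[dict[int, int]], n_sites: int
) -> np.ndarray:
    """All minimum-error-correction optimal haplotype bipartitions.

    Enumerates all 2^(n-1) assignments of each site's ALT allele to one of
    two haplotypes, scores each as the summed per-fragment minimum Hamming
    distance to either haplotype (missing sites ignored), and returns every
    optimal assignment as rows of a (k, n_sites) 0/1 array.

    Fragment alleles: 0 = REF, 1 = ALT; missing sites simply absent.
    """
    F = len(fragments)
    A = np.full((max(F, 1), n_sites), -1, dtype=np.int8)
    for i, frag in enumerate(fragments):
        for s, allele in frag.items():
            A[i, s] = allele
    mask = A >= 0
    # fix site 0's alt on haplotype 1 to halve the search space
    codes = np.arange(2 ** (n_sites - 1), dtype=np.int64)
    H = np.zeros((len(codes), n_sites), dtype=np.int8)
    for s in range(1, n_sites):
        H[:, s] = (codes >> (s - 1)) & 1
    H[:, 0] = 1
    diff1 = (A[None, :, :] != H[:, None, :]) & mask[None, :, :]
    diff2 = (A[None, :, :] != (1 - H)[:, None, :]) & mask[None, :, :]
    err = np.minimum(diff1.sum(axis=2), diff2.sum(axis=2)).sum(axis=1)
    return H[err == err.min()]


def mec_relative_phase_from_optima(optima: np.ndarray, a: int, b: int) -> str | None:
    """'cis'/'trans' read off the MEC optima, or None when optima disagree
    (the phase is not determined by the data)."""
    phases = {("cis" if h[a] == h[b] else "trans") for h in optima}
    return phases.pop() if len(phases) == 1 else None


def mec_relative_phase(
    fragments: list[dict[int, int]], n_sites: int, a: int, b: int
) -> str | None:
    """Relative phase of sites a, b under minimum-error-correction."""
    if not fragments:
        return None
    return mec_relative_phase_from_optima(
        mec_optimal_haplotypes(fragments, n_sites), a, b
    )
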