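# Methods

`lramp` supports the computational side of a long-range (LR) PCR amplicon
sequencing workflow for Mendelian diagnostics: LR PCRs of up to ~20 kb tile
entire disease loci (introns and promoters included), the amplicons are
pooled, sheared and sequenced paired-end, and the resulting reads support
variant detection, cis/trans phasing of candidate compound-heterozygous
variants, and nucleotide-resolution characterization of deletion CNV
breakpoints. This note records the models, the parameters that matter, and
the design decisions taken where the design was genuinely open.

## Coordinates and panel accounting

All in-memory coordinates are 1-based inclusive (the HGVS g. convention, in
which every clinically reported coordinate is printed); BED input/output
converts at the file boundary, and an interval `[start, end]` contains
`end − start + 1` bases. This single convention removes the main class of
off-by-one errors in breakpoint arithmetic.

A panel is a set of loci, each tiled by amplicons that may overlap their
neighbours. Per-locus *genomic target size* is the size of the union of the
locus' amplicon intervals (overlaps counted once); the panel total is the
sum over loci, which requires loci to be pairwise disjoint — enforced at
load, since overlapping loci would make target attribution ambiguous.
Gaps are the maximal sub-intervals of a locus target covered by no
amplicon; overlap regions are the maximal intervals covered by ≥2
amplicons (computed by an endpoint sweep-line). Strand is ignored
throughout: the accounting concerns genomic spans only, and primer
orientation is kept as metadata.

The bundled 35-locus retinal-disease panel ships as published per-locus
target sizes and PCR counts. Exact amplicon coordinates are not part of the
published design, so each locus is represented as one interval of the
published size; all size accounting is exact under this representation,
while gap/overlap queries on this particular fixture are trivially empty.

Allele dropout (ADO): a deletion that removes a primer-binding site
prevents amplification of that allele, so the assay sees only the intact
haplotype — no CNV signal beyond reduced yield and uniformly
homozygous-appearing genotypes. `ado_risk` flags any amplicon whose primer
site intersects a candidate deletion and any amplicon wholly contained in
it; when the panel records no primer spans, the check degrades to the
amplicon end coordinates and says so. The complementary screen,
`homozygosity_warning`, flags regions where ≥ `min_sites` (default 5)
variant calls are all homozygous. Both screens are heuristic:
no thresholds exist in the protocol being automated, so the defaults are
deliberate, conservative automation choices and are exposed on the CLI.

## Pooling stoichiometry

All calculators are exact arithmetic with one physical constant: 660
g·mol⁻¹·bp⁻¹ for double-stranded DNA, giving library molarity
`nM = conc[ng/µL] × 10⁶ / (660 × fragment_bp)`.

* Dilutions follow C₁V₁ = C₂V₂; upward "dilution" is an error.
* Amplicon pools assume a common working concentration (default 10 ng/µL)
  and assign volumes proportional to amplicon size, with a minimum total
  (default 130 µL, the shearing-tube volume). Size-proportional volumes at
  equal mass concentration make the pool equimolar per template copy, so
  every base position of every amplicon is equally represented.
* Indexed libraries normalized to a common molarity (4 nM working
  concentration) are pooled proportionally to their genomic target sizes,
  balancing reads per target base across samples.
* WES spike-in is the pure ratio `amount × lr_target / wes_target`,
  unit-agnostic (attomoles, nanograms, or fractions).

Volumes are rounded to 0.1 µL (a pipettable increment); the rounding
residue lands on the largest component so totals are exact. A per-component
floor (default 1 µL) may raise a pool above its minimum total; the plan's
header notes record which regime applied.

## Read-backed phasing

Two recessive candidate variants cause disease only in trans. When no
relatives are available, fragments (read pairs, merged by read name) that
co-observe heterozygous sites decide the question. Per site pair
co-observed by a fragment: equal alleles (ALT,ALT *or* REF,REF) are one cis
observation, unequal alleles one trans observation. REF,REF counts as cis
evidence because both sites are heterozygous — a doubly-REF fragment is the
other haplotype intact. Evidence chains transitively: the relative phase of
two sites joined by a path is the XOR of edge parities along it (trans = 1;
two trans edges compose to cis).

Edges are retained with the majority parity plus support (majority count)
and conflict (minority count) tallies. A call requires every edge on the
connecting path to clear `min_support` (default 2 fragments) and
`max_conflict_fraction` (default 0.2); additionally, if the connected
component containing the two query sites has *any* parity-inconsistent
cycle, the pair is reported unresolved with a diagnostic rather than
majority-voted — in a diagnostic setting an overcall is worse than no
call. Base and mapping quality floors (default 20/20) turn individual read
bases into MISSING before they can vote; mates that contradict each other
at a site blank that site for the fragment. Indel alleles are matched by
the presence or absence of the corresponding insertion/deletion operation
at the site in the read alignment (left-aligned indels are assumed from
upstream calling), not by local re-alignment.

The automated procedure replaces manual inspection of read stacks in a
viewer, so none of these thresholds has a published value; all are exposed
as CLI flags. Chain length is unbounded by default. The test suite checks
the parity construction against an exhaustive minimum-error-correction
(MEC) oracle: enumerate all 2^(n−1) haplotype bipartitions, score each by
summed per-fragment Hamming distance to the nearer haplotype, and read the
pair's phase off the optimum. Confident graph calls agree with the unique
MEC optimum on 100% of ~1,000 seeded random instances (≤10 sites, ≤30
fragments, with and without 5% allele noise).

## Deletion breakpoints and microhomology

Given a reference segment and an observed breakpoint-spanning sequence
(a deletion-spanning amplicon consensus or assembled contig — producing it
from raw reads is upstream alignment/assembly work, outside this package),
the single clean deletion relating them is characterized by longest common
prefix/suffix (LCP/LCS) algebra. With reference length R, observed length
O, LCP p and LCS s:

* the pair is explainable by one contiguous deletion iff `p + s ≥ O`
  (otherwise a substitution or junction insertion is present and the
  operation refuses with "not a clean deletion");
* deletion length `D = R − O`, identical for every placement;
* microhomology length `m = p + s − O` — the placement slack, which equals
  the length of the identical sequence shared by the two flanks;
* the deletion may start at any of the `m + 1` positions
  `O − s + 1 … p + 1`; the 5′ interval of possible starts and the 3′
  interval of corresponding ends each have inclusive length `m + 1`.

`N` bases never match in the LCP/LCS extension: under ambiguity the
conservative reading is less homology, not more.

HGVS rendering defaults to the ambiguous-interval form
`contig:g.(a_b)_(c_d)del` whenever `m > 0`, because within a microhomology
the true breakpoint is genuinely unknowable from sequence alone; the
3′-most placement (the HGVS shifting rule) is available by flag, and the
exact form is used when the placement is unique. The ambiguous string
parses back to the placement intervals (round-trip tested). Flanking
repeats (e.g. Alu elements, the classic substrates of recombination-
mediated deletions) are labeled 5′-side, 3′-side or internal relative to
the placement intervals within a configurable window.

Homopolymer-aware placement (when one breakpoint "probably lies within" an
A-rich run) is not attempted: the placement set already encodes exactly
what the sequence supports, and guessing further would manufacture
precision. Junction insertions (complex events) raise an error rather than
risk a mis-reported deletion.

## Depth QC

Depth counts aligned read bases per reference position (CIGAR-aware:
read-deleted bases contribute nothing; inserted bases consume no
reference), matching what a coverage track displays. Secondary,
supplementary, unmapped and duplicate-flagged records are excluded; no
duplicate marking is performed, since amplicon libraries are PCR-derived
and duplicates are expected and kept. Gap reporting returns maximal
intervals below `min_depth` (default 20×). Files are streamed, so
plain-text SAM without an index works.

## Synthetic data

The simulators generate every fixture the package needs, with byte-
identical output for identical (seed, scenario):

* random uniform-composition references;
* planted deletions with an *exactly* specified microhomology: the 3′
  flank's first `m` bases are rewritten to copy the deleted segment's
  first `m` bases, then the first base beyond the homology on each side is
  forced to mismatch, so chance extension cannot enlarge the placement set
  and truth records are exact;
* two-haplotype paired-read sets: 2×151 bp reads, insert 375 ± 25 bp
  (truncated to [read length, haplotype length]), equal haplotype
  sampling, substitution-only errors, emitted as already-aligned SAM
  records whose CIGARs are derived from the haplotype-to-reference
  coordinate map (SNV, insertion and deletion variants supported), plus a
  truth table of fragment origins and a genotyped truth VCF;
* per-amplicon read pools in two modes: `random` (paired reads, realistic
  ramped amplicon edges) and `uniform` (successive end-to-end tilings of
  single reads, trimmed at amplicon boundaries, giving exactly `depth` at
  every amplicon base — the noiseless mode in which overlap regions carry
  exactly doubled depth).

What the simulations do **not** emulate: PCR chimeras and polymerase
error profiles, indel sequencing errors, quality-score miscalibration,
alignment ambiguity in repeats (reads are placed by construction), and
real haplotype structure. Passing tests therefore demonstrate the
correctness of the algebra and the automation on idealized reads, not
end-to-end performance on patient libraries; cohort-scale sensitivity
claims are out of reach at desk scale by design.

## Problem sizes in the checks

The acceptance script and test suite run: ~1,000 (tests) / 500 (script)
random phasing instances against the exhaustive MEC oracle; 200 random ≤2 kb
sequences against exhaustive removal-and-compare placement enumeration; 100
clean planted-deletion recoveries (deletions 50–5,000 bp, microhomology
0–12 bp); one 70 kb planted deletion recovered on a 75 kb toy contig; and a
compound-heterozygous simulation with two indel candidates 19 bp apart on
opposite haplotypes at 60× — sizes chosen to exercise every code path many
times while keeping the whole suite under ten seconds.

## Known limitations

* The phase graph answers pairwise queries through reliable chains; it is
  not a whole-locus haplotype assembler and deliberately refuses
  parity-inconsistent components instead of optimizing through them.
* `infer_deletion` assumes the observed sequence differs from the
  reference segment by exactly one deletion; flank mismatches (real
  variants or sequencing errors in the consensus) cause a refusal rather
  than a fuzzy call.
* The bundled panel fixture carries published per-locus sizes, not real
  amplicon coordinates, so it exercises size accounting only.
* Pool plans assume measured concentrations are accurate and PCR
  efficiency is uniform; no efficiency modeling is attempted.
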