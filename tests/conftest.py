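import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lramp.intervals import GenomicInterval
from lramp.panel import Amplicon, AmpliconPanel, Locus


@pytest.fixture
def overlap_panel() -> AmpliconPanel:
    """Two amplicons overlapping on [951, 1000] of a single locus."""
    a1 = Amplicon("A1", GenomicInterval("chrT", 1, 1000))
    a2 = Amplicon("A2", GenomicInterval("chrT", 951, 2000))
    return AmpliconPanel([Locus("LOC", (a1, a2))])


@pytest.fixture
def primer_panel() -> AmpliconPanel:
    """One locus, two amplicons with 28 bp primer sites at their ends."""
    def amp(name, start, end):
        return Amplicon(
            name,
            GenomicInterval("chrP", start, end),
            fwd_primer_site=GenomicInterval("chrP", start, start + 27),
            rev_primer_site=GenomicInterval("chrP", end - 27, end),
        )
    return AmpliconPanel([Locus("GENE", (amp("G_1", 1000, 6000), amp("G_2", 5800, 11000)))])
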