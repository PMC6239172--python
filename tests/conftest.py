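import numpy as np
import pytest

from primarytx.genome_io import GeneFeature, Genome
from primarytx.tss_caller import TssRecord


def make_tss(position, strand="+", density=10.0, replicon="chr",
             enrichment=5.0, conditions=("H20",), **kw):
    return TssRecord(
        replicon=replicon, strand=strand, position=position, density=density,
        enrichment=enrichment, conditions=set(conditions), **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def flat_genome():
    """10 kb of A's with an ATG planted wherever tests put genes."""
    return Genome({"chr": "A" * 10000})


@pytest.fixture
def archetype_setup():
    """A genome with one unambiguous instance of each TSS category relation.

    Layout (all on 'chr', 20 kb):
      g1  + strand [1000, 2000): primary TSS at 950, secondary at 940 (lower
          density), internal TSS at 1500 (+), antisense TSS at 1500 (-)
      g2  - strand [5000, 6000): primary TSS at 6049 (upstream on -)
      intergenic TSS at 9000 (no feature within reach)
      g5/g6 overlapping-window pair for the tie case: both + strand,
          start codons at 12000 and 12200; a TSS at 12100 is equidistant
          from both start codons and inside both windows, so the
          lexicographically smaller gene id (g5) wins.
    """
    rng = np.random.default_rng(0)
    seq = list("".join(rng.choice(list("ACGT"), size=20000)))
    for pos in (1000, 12000, 12200):
        seq[pos:pos + 3] = list("ATG")
    seq[6000 - 3:6000] = list("CAT")  # - strand start codon (revcomp ATG)
    genome = Genome({"chr": "".join(seq)})
    genes = [
        GeneFeature("g1", "chr", "+", 1000, 2000),
        GeneFeature("g2", "chr", "-", 5000, 6000),
        GeneFeature("g5", "chr", "+", 12000, 12150),
        GeneFeature("g6", "chr", "+", 12200, 12800),
    ]
    tss = {
        "P": make_tss(950, "+", density=100.0),
        "S": make_tss(940, "+", density=40.0),
        "I": make_tss(1500, "+", density=20.0),
        "A": make_tss(1500, "-", density=20.0),
        "N": make_tss(9000, "+", density=20.0),
        "P2": make_tss(6049, "-", density=80.0),
        "tie": make_tss(12100, "+", density=60.0),
    }
    return genome, genes, tss
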