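import pandas as pd
import pytest

from cutac.genome import (Arm, GeneAnnotation, GenomeModel, HISTONE_SET,
                          RIBOSOMAL_SET)
from cutac.simulate import miniature_genome


@pytest.fixture(scope="session")
def genome():
    """The packaged miniature genome (treated as read-only)."""
    return miniature_genome()


def make_tiny_genome(length=10_000, centromere=6_000, ccres=None, genes=None,
                     lines=None, mito_len=500):
    """Hand-sized single-autosome genome for unit tests."""
    ccres = ccres if ccres is not None else [("chr1", 100, 200, "c1", "PLS")]
    genes = genes if genes is not None else [
        GeneAnnotation("gA", "chr1", "+", [100], [300]),
        GeneAnnotation("gB", "chr1", "-", [400], [700]),
    ]
    lines = lines if lines is not None else []
    return GenomeModel(
        chrom_sizes={"chr1": length, "chrM": mito_len},
        mito_name="chrM",
        arms=[Arm("chr1", "p", 0, centromere),
              Arm("chr1", "q", centromere, length)],
        ccres=pd.DataFrame(ccres, columns=["chrom", "start", "end", "id",
                                           "category"]),
        genes=genes,
        lines=pd.DataFrame(lines, columns=["chrom", "start", "end"]),
        gene_sets={HISTONE_SET: [genes[0].gene_id],
                   RIBOSOMAL_SET: [genes[-1].gene_id]},
    )


@pytest.fixture
def tiny_genome():
    return make_tiny_genome()


def frame_from_fragments(frags):
    return pd.DataFrame(frags, columns=["chrom", "start", "end"])
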