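import numpy as np
import pytest

from paraloc.locus_io import ContigSequence, GeneModel, ParalogueLocus
from paraloc.synthetic_locus import FamilyConfig, generate_family


@pytest.fixture(scope="session")
def family():
    """Default six-gene synthetic locus (study-scale, ~603 kb)."""
    return generate_family(FamilyConfig(seed=1))


@pytest.fixture(scope="session")
def small_family():
    """Compact family for fast per-variant and amplicon tests."""
    cfg = FamilyConfig(n_genes=4, cds_len=942, intron_len=300,
                       intergenic_len=3000, seed=2)
    return generate_family(cfg)


@pytest.fixture
def toy_locus():
    """Two tiny genes, one per strand, on a handcrafted contig.

    plus-strand geneP: exons [10,19); CDS ATGTGTTAC (M C Y)
    minus-strand geneM: exons [30,39); CDS ATGAAATAA (M K *) stored
    reverse-complemented on the contig.
    """
    cds_p = "ATGTGTTAC"
    cds_m = "ATGAAATAA"
    residues = (
        "A" * 10 + cds_p + "C" * 11
        + "TTATTTCAT"  # revcomp(cds_m)
        + "G" * 11
    )
    contig = ContigSequence("toy", residues)
    genes = {
        "geneP": GeneModel("geneP", "+", [(10, 19)]),
        "geneM": GeneModel("geneM", "-", [(30, 39)]),
    }
    return ParalogueLocus(contig, genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
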