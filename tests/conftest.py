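import numpy as np
import pytest

from clipshift.annotation import (
    GeneModel,
    GenomeAnnotation,
    IntronCatalog,
    Transcript,
    genic_partition,
)
from clipshift.simulate import make_toy_reference


@pytest.fixture(scope="session")
def toy_ref():
    """Default toy genome: 50 genes, fixed seed."""
    return make_toy_reference(50, seed=1)


@pytest.fixture(scope="session")
def toy_partition(toy_ref):
    return genic_partition(toy_ref.annotation)


@pytest.fixture(scope="session")
def toy_introns(toy_ref):
    return IntronCatalog.from_annotation(toy_ref.annotation)


@pytest.fixture
def two_gene_annotation():
    """Hand-built two-gene annotation with known partition.

    geneA (+): exons [100,200) and [300,400), CDS [150,350); intron [200,300).
    geneB (-): single exon [1000,1300), CDS [1100,1250).
    """
    gene_a = GeneModel(
        "geneA", "chr1", "+",
        [Transcript("geneA.t1", [(100, 200), (300, 400)], (150, 350))],
    )
    gene_b = GeneModel(
        "geneB", "chr1", "-",
        [Transcript("geneB.t1", [(1000, 1300)], (1100, 1250))],
    )
    return GenomeAnnotation([gene_a, gene_b], {"chr1": 2000})


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
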