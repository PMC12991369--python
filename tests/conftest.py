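import numpy as np
import pytest

from connis.genome import GeneSet, InsertionSiteSet


@pytest.fixture
def toy_genome():
    """100 bp genome: IS saturating positions 51..60, two contrasting genes."""
    iss = InsertionSiteSet(100, np.arange(51, 61))
    genes = GeneSet(["g1", "g2"], [1, 51], [50, 60], genome_length=100)
    return genes, iss


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
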