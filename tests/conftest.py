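import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from meriphmm import BinCounts, GeneModel, HMMParams


@pytest.fixture
def study_params() -> HMMParams:
    """The transition structure used throughout the validation study."""
    return HMMParams(pi=0.2, A=np.array([[0.7, 0.3], [0.1, 0.9]]),
                     p=np.array([0.2, 0.8]))


@pytest.fixture
def two_exon_gene() -> GeneModel:
    return GeneModel(gene_id="g1", chrom="chr1", strand="+",
                     exons=[(100, 200), (300, 400)])


def random_chain(rng, n_max=10, t_max=15):
    """A random small chain and random valid parameters, for oracle tests."""
    n = int(rng.integers(1, n_max + 1))
    t = rng.integers(0, t_max + 1, size=n)
    x = rng.binomial(t, rng.uniform(0.1, 0.9))
    a1, a2 = rng.uniform(0.05, 0.95, size=2)
    p1 = rng.uniform(0.05, 0.45)
    p2 = rng.uniform(p1 + 0.05, 0.95)
    params = HMMParams(pi=float(rng.uniform(0.05, 0.95)),
                       A=np.array([[a1, 1 - a1], [a2, 1 - a2]]),
                       p=np.array([p1, p2]))
    counts = BinCounts(gene_id="rand", x=x, y=t - x)
    return counts, params
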