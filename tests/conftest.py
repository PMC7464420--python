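import numpy as np
import pytest

from greyscan.bayescan_engine import MCMCConfig
from greyscan.genotype_io import MISSING, GenotypeDataset, LocusInfo


@pytest.fixture
def tiny_loci():
    return [
        LocusInfo("14", "snp1", 22_986_080),
        LocusInfo("14", "snp2", 23_630_896),
        LocusInfo("2", "snp3", 6_760_630),
    ]


@pytest.fixture
def tiny_dataset(tiny_loci):
    """4 individuals (2 breeds) x 3 loci with mixed missingness.

    Orientation is canonical (the first non-missing call at each locus
    carries the A allele), as produced by read_ped_map.
    """
    calls = np.array(
        [
            [1, 1, 2],
            [0, MISSING, 2],
            [2, 2, MISSING],
            [MISSING, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeDataset(
        individuals=[("i1", "Grey"), ("i2", "Grey"), ("i3", "Ref"), ("i4", "Ref")],
        loci=tiny_loci,
        calls=calls,
        allele_labels=[("A", "G"), ("C", "T"), ("A", "C")],
    )


@pytest.fixture
def short_chain():
    """Chain settings short enough for unit tests, long enough to mix."""
    return MCMCConfig(
        n_pilot=4, pilot_length=300, burn_in=1000, n_samples=2000, thinning=1, seed=7
    )
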