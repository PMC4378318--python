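import numpy as np
import pytest

import redseq as rs


@pytest.fixture
def sau96i() -> rs.EnzymeSpec:
    return rs.BUILTIN_ENZYMES["Sau96I"]


@pytest.fixture
def ddei() -> rs.EnzymeSpec:
    return rs.BUILTIN_ENZYMES["DdeI"]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_index(positions, enzyme=None, chrom="chr1", variant="GGTCC", chrom_size=None):
    """Toy index with Sau96I sites at the given motif_start positions."""
    enzyme = enzyme or rs.BUILTIN_ENZYMES["Sau96I"]
    sites = [
        rs.RestrictionSite(i, chrom, int(p), enzyme.name, variant)
        for i, p in enumerate(positions)
    ]
    sizes = {chrom: chrom_size or (max(positions) + 100)}
    return rs.RSIndex.from_sites(sites, [enzyme], chrom_sizes=sizes)


@pytest.fixture
def toy_index():
    return make_index([100, 300, 700, 1500])
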