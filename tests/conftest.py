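import numpy as np
import pytest

from adaptscan.datatypes import GenotypeMatrix, PopulationPanel


def make_matrix(haps, pos=None, ancestral="ref", sample_prefix="S", chrom="1"):
    """Build a small GenotypeMatrix from a (2n x m) 0/1 array."""
    haps = np.asarray(haps, dtype=np.int8)
    n2, m = haps.shape
    assert n2 % 2 == 0
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    ref = np.array(["A"] * m, dtype=object)
    alt = np.array(["G"] * m, dtype=object)
    aa = None
    if ancestral == "ref":
        aa = ref.copy()
    elif ancestral == "alt":
        aa = alt.copy()
    return GenotypeMatrix(
        variant_ids=np.array([f"v{j}" for j in range(m)], dtype=object),
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=ref,
        alt_allele=alt,
        haplotypes=haps,
        sample_ids=np.array([f"{sample_prefix}{i}" for i in range(n2 // 2)], dtype=object),
        ancestral_allele=aa,
        phased=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pop_matrix(rng):
    """10 diploids split into two populations, 30 random SNPs."""
    haps = (rng.random((20, 30)) < rng.uniform(0.1, 0.9, 30)).astype(np.int8)
    gm = make_matrix(haps)
    panel = PopulationPanel(
        {f"S{i}": ("POPA" if i < 5 else "POPB") for i in range(10)},
        {"POPA": "X", "POPB": "X"},
    )
    return gm, panel
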