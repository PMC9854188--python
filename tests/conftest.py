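import numpy as np
import pytest

from csscan.genotype_io import HaplotypeSet, MarkerMap


def make_map(positions, chrom="1", ref="A", alt="G"):
    n = len(positions)
    if isinstance(chrom, str):
        chrom = [chrom] * n
    return MarkerMap(
        np.array(chrom, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array([f"{c}.{p}" for c, p in zip(chrom, positions)], dtype=object),
        np.array([ref] * n, dtype=object),
        np.array([alt] * n, dtype=object),
    )


def make_haps(alleles, phased=True, prefix="S"):
    alleles = np.asarray(alleles, dtype=np.int8)
    ids = [f"{prefix}{i + 1}" for i in range(alleles.shape[0] // 2)]
    return HaplotypeSet(alleles, ids, phased=phased)


def random_panel(rng, n_samples, n_snps, chrom="1", spacing=1000):
    """Random complete phased panel on one chromosome."""
    pos = np.cumsum(rng.integers(1, 2 * spacing, size=n_snps))
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    alleles = (rng.random((2 * n_samples, n_snps)) < freqs).astype(np.int8)
    return make_haps(alleles), make_map(pos, chrom=chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_panel():
    """4 samples x 5 SNPs, complete and phased."""
    alleles = np.array(
        [
            [0, 1, 0, 0, 1],
            [0, 1, 1, 0, 1],
            [1, 0, 0, 0, 1],
            [0, 0, 1, 0, 1],
            [0, 1, 0, 1, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 0, 0, 1],
            [1, 1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return make_haps(alleles), make_map([100, 2500, 4000, 7000, 12000])
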