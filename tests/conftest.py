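import numpy as np
import pytest

from medpopgen.containers import GenotypeTable, HaplotypeSet, VariantSite
from medpopgen.simulate import SimConfig, simulate_neutral_population


def make_sites(positions, chrom="chr1", ancestral="A"):
    return [VariantSite(chrom, int(p), "A", ("T",), ancestral) for p in positions]


def make_haps(matrix, positions=None, chrom="chr1"):
    """HaplotypeSet from a 0/1 matrix (rows = haplotypes)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    if positions is None:
        positions = np.arange(matrix.shape[1]) * 1000
    assert matrix.shape[0] % 2 == 0
    samples = [f"s{i}" for i in range(matrix.shape[0] // 2)]
    return HaplotypeSet(make_sites(positions, chrom), samples, matrix)


def make_table(genotypes, positions=None, samples=None, chrom="chr1", n_alts=1):
    """GenotypeTable from an (n_samples, n_sites, 2) array."""
    genotypes = np.asarray(genotypes, dtype=np.int16)
    n_samples, n_sites, _ = genotypes.shape
    if positions is None:
        positions = np.arange(n_sites) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    alts = tuple("TGC"[:n_alts])
    sites = [VariantSite(chrom, int(p), "A", alts) for p in positions]
    return GenotypeTable(sites, samples, genotypes)


@pytest.fixture(scope="session")
def wild_population():
    """A small neutral wild-type sample reused across read-only tests."""
    return simulate_neutral_population(
        SimConfig(seed=42, sequence_length=300_000, n_haplotypes=32)
    )
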