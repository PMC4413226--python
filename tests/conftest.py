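import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from haplorefine.io import GeneticMap, GenotypeLikelihoods, ScaffoldHaplotypes
from haplorefine.simulate import likelihoods_from_read_counts

# haplotype background patterns for the 4-individual rescue fixture
_A = [1, 1, 0, 0, 1, 1]
_B = [0, 0, 0, 0, 0, 0]
_C = [0, 1, 0, 1, 0, 1]
_D = [1, 0, 1, 0, 1, 0]
_E = [1, 1, 1, 1, 1, 1]


@pytest.fixture
def rescue_fixture():
    """Four-diploid cohort where an ambiguous individual (1 alt read of 8,
    maximum-likelihood call hom-ref) shares its first haplotype background
    with a confidently heterozygous individual, and every other haplotype is
    anchored to a confident homozygous-reference carrier."""
    alleles = np.array([_A, _C, _A, _B, _B, _D, _C, _E])
    scaffold = ScaffoldHaplotypes(alleles, ["proband", "het", "ref1", "ref2"])
    gmap = GeneticMap([1000, 2000, 3000, 4000, 5000, 6000],
                      np.arange(6) * 0.001)
    ambiguous = likelihoods_from_read_counts(8, 1, 0.01).values[0]
    lik = GenotypeLikelihoods(np.array([
        ambiguous,
        [1e-8, 1.0, 1e-8],
        [1.0, 1e-8, 1e-16],
        [1.0, 1e-8, 1e-16],
    ]))
    return scaffold, gmap, lik, 3500


def random_small_pool(rng):
    """Random pool with <= 4 haplotypes (2 individuals) and <= 6 markers,
    with a random genetic map — instances small enough for path enumeration."""
    n_ind = int(rng.integers(1, 3))
    m = int(rng.integers(2, 7))
    alleles = rng.integers(0, 2, size=(2 * n_ind, m))
    scaffold = ScaffoldHaplotypes(alleles, [f"i{j}" for j in range(n_ind)])
    positions = np.sort(rng.choice(np.arange(1, 100_000), size=m, replace=False))
    cm = np.cumsum(rng.random(m) * 0.2)
    cm -= cm[0]
    gmap = GeneticMap(positions, cm)
    lam = float(10 ** rng.uniform(-7, -0.5))
    ne = float(10 ** rng.uniform(0, 4))
    return scaffold, gmap, lam, ne
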