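import numpy as np
import pytest

from wrenfit.relatedness import frequencies_from_vectors
from wrenfit.simdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete population (fast to simulate)."""
    return SimConfig(n_territories=25, n_years=6, burnin_years=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def equifreq_loci():
    """8 microsatellite-like loci with 30 equifrequent alleles."""
    loci = [f"L{i}" for i in range(8)]
    freqs = frequencies_from_vectors(loci, [np.full(30, 1 / 30)] * 8)
    return loci, freqs


def draw_genotypes(rng, n, n_loci=8, n_alleles=30):
    """Random Hardy-Weinberg genotypes, codes 1..n_alleles."""
    return rng.integers(1, n_alleles + 1, size=(n, n_loci, 2))


def mate(rng, dam, sire):
    """Mendelian offspring of two (n, L, 2) genotype arrays."""
    n, L, _ = dam.shape
    pick_d = rng.integers(0, 2, size=(n, L))
    pick_s = rng.integers(0, 2, size=(n, L))
    return np.stack(
        [
            np.take_along_axis(dam, pick_d[..., None], axis=2)[..., 0],
            np.take_along_axis(sire, pick_s[..., None], axis=2)[..., 0],
        ],
        axis=2,
    )
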