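import numpy as np
import pytest

from kinid.fixtures import sibling_pedigree, washington_pedigree
from kinid.genetic_map import GeneticMap
from kinid.synthetic import gene_drop, generate_frequency_panel


@pytest.fixture(scope="session")
def gmap():
    return GeneticMap()


@pytest.fixture(scope="session")
def washington():
    return washington_pedigree()


@pytest.fixture(scope="session")
def small_panel():
    """3000 autosomal + 60 X + 40 Y sites, one population."""
    return generate_frequency_panel(3000, 60, 40, populations=["EUR"], seed=11)


@pytest.fixture(scope="session")
def trio_drop(small_panel):
    """Gene-dropped genotypes for a two-child nuclear family."""
    ped = sibling_pedigree(2)
    return gene_drop(ped, small_panel, seed=21)


def simulate_gl_pair(k, p, mean_depth, rng, base_error=0.001):
    """Fast direct simulation of a GL-profile pair under a k-triple.

    Genotypes are drawn site-wise from the Cotterman mixture (IBD2: shared
    genotype, IBD1: one shared allele, IBD0: independent HWE), reads are
    Poisson with symmetric base error, and the closed-form biallelic GL
    triple is returned as two (n, 3) log arrays plus coverage vectors.
    """
    n = len(p)
    state = rng.choice(3, size=n, p=k)

    def bern():
        return (rng.random(n) < p).astype(np.int8)

    a1, a2, extra = bern(), bern(), bern()
    ga = a1 + a2
    shared = np.where(rng.random(n) < 0.5, a1, a2)
    gb = np.where(
        state == 2, ga,
        np.where(state == 1, shared + extra, bern() + bern()),
    )
    gls = []
    covs = []
    for g in (ga, gb):
        depth = rng.poisson(mean_depth, n)
        p_alt_read = g / 2.0
        p_obs_alt = p_alt_read * (1 - base_error) + (1 - p_alt_read) * base_error
        n_alt = rng.binomial(depth, p_obs_alt)
        n_ref = depth - n_alt
        e = base_error
        log_l = np.stack(
            [
                n_ref * np.log(1 - e) + n_alt * np.log(e),
                depth * np.log(0.5),
                n_ref * np.log(e) + n_alt * np.log(1 - e),
            ],
            axis=1,
        )
        gls.append(log_l)
        covs.append(depth)
    return gls[0], gls[1], covs[0], covs[1]


@pytest.fixture(scope="session")
def gl_pair_simulator():
    return simulate_gl_pair
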