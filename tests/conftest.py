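import numpy as np
import pytest

from sweepdann.nn import ArchitectureSpec, ConvBlock
from sweepdann.sim import Demography, HaplotypeSample, SimParams, WFPopulation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_params():
    """Small, fast locus used for unit tests (per-bp 4N*mu = 0.005 at N=100)."""
    return SimParams(L=5000.0, mu=1.25e-5, r=1.25e-5, n_sample=10, seed=7)


@pytest.fixture
def toy_spec():
    return ArchitectureSpec(
        input_shape=(10, 32),
        blocks=(ConvBlock(4), ConvBlock(8)),
        label_hidden=(16,),
        domain_hidden=(16,),
    )


def make_sample(alleles, positions=None, L=100.0, label="neutral", domain="source"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if positions is None:
        positions = np.linspace(1.0, L - 1.0, alleles.shape[1])
    return HaplotypeSample(
        positions=np.asarray(positions, dtype=float),
        alleles=alleles,
        label=label,
        domain=domain,
        params=SimParams(L=L, mu=0.0, r=0.0, n_sample=alleles.shape[0] // 2),
    )


def focal_population(n_diploid, p0, L=1000.0, rng=None, focal_pos=500.0):
    """Population with no polymorphic background and one tracked focal site
    at derived frequency p0 (rounded to a whole count)."""
    n_hap = 2 * n_diploid
    focal = np.zeros(n_hap, dtype=np.uint8)
    count = int(round(p0 * n_hap))
    if rng is None:
        focal[:count] = 1
    else:
        focal[rng.choice(n_hap, size=count, replace=False)] = 1
    pop = WFPopulation(
        np.zeros((n_hap, 0), dtype=np.uint8), np.empty(0), L,
        focal=focal, focal_pos=focal_pos,
    )
    return pop
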