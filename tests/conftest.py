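import numpy as np
import pytest

from plastisim.genetics import N_ALLELES, Genotype
from plastisim.population import Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotype(sum_n=0.0, sum_p=0.0, sum_d=None):
    """Genotype whose class sums are given, spread evenly over alleles."""
    return Genotype(
        nonplastic=np.full(N_ALLELES, sum_n / N_ALLELES),
        plastic=np.full(N_ALLELES, sum_p / N_ALLELES),
        instability=None if sum_d is None else np.full(N_ALLELES, sum_d / N_ALLELES),
    )


def make_population(sum_p, demes, sum_d=None, sum_n=0.0):
    """Population with per-individual class sums spread evenly over alleles.

    ``sum_p`` and (optionally) ``sum_d`` are per-individual values; ``demes``
    assigns each individual to a deme.
    """
    sum_p = np.asarray(sum_p, dtype=float)
    demes = np.asarray(demes, dtype=np.int64)
    n = sum_p.size
    inst = None
    if sum_d is not None:
        inst = np.repeat(
            np.asarray(sum_d, dtype=float)[:, None] / N_ALLELES, N_ALLELES, axis=1
        )
    return Population(
        nonplastic=np.full((n, N_ALLELES), sum_n / N_ALLELES),
        plastic=np.repeat(sum_p[:, None] / N_ALLELES, N_ALLELES, axis=1),
        instability=inst,
        phenotype=np.full(n, np.nan),
        deme=demes,
        natal_deme=demes.copy(),
    )
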