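import numpy as np
import pytest

from plastomekit.simulate import (SyntheticSpec, arrangement_genomes,
                                  gene_status_genome, generate_plastome,
                                  isomer_fixture)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_quadripartite():
    """20 kb genome with a 1.5 kb IR and a few genes, reused widely."""
    from plastomekit.simulate import GeneSpec
    spec = SyntheticSpec(
        seed=42, lsc_len=12000, ssc_len=4000, ir_len=1500,
        genes=(GeneSpec("rbcL", "PCG", "LSC", 600),
               GeneSpec("accD", "PCG", "LSC", 900),
               GeneSpec("trnM", "tRNA", "IR", 75),
               GeneSpec("ndhF", "PCG", "SSC", 450, strand="-")))
    return generate_plastome(spec)


@pytest.fixture(scope="session")
def status_fixture():
    """Genome with 4 genes planted under each of the five statuses."""
    return gene_status_genome(seed=3, per_status=4)


@pytest.fixture(scope="session")
def arrangement_fixture():
    return arrangement_genomes(seed=11)


@pytest.fixture(scope="session")
def isomer_pair_fixture():
    return isomer_fixture(seed=23)
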