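import numpy as np
import pytest

from strainrec.genomes import GenotypeMatrix
from strainrec.pipeline import simulate_study
from strainrec.synthesizer import SimulationConfig

#: desk-scale conditions for module tests: same structure as the default
#: study, trimmed so the whole suite trains several resources in seconds
SMALL = SimulationConfig(n_donors=60, n_strains=12, n_genes=40, n_variants=600,
                         chrom_length=6_000_000, block_length=1_000_000,
                         n_signature_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SMALL)


@pytest.fixture(scope="session")
def default_study():
    """The default-scale synthetic study used by the acceptance checks."""
    return simulate_study(SimulationConfig(seed=1))


def make_gm(dosage, pos=None, chrom="1", samples=None, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    v, s = dosage.shape
    if pos is None:
        pos = np.arange(1, v + 1) * 1000
    if samples is None:
        samples = [f"S{i}" for i in range(s)]
    if ids is None:
        ids = [f"v{i}" for i in range(v)]
    return GenotypeMatrix(np.array(ids, dtype=object),
                          np.full(v, chrom, dtype=object),
                          np.asarray(pos), samples, dosage)


@pytest.fixture
def gm_factory():
    return make_gm
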