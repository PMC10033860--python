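import numpy as np
import pytest

from mhcds.io_formats import AlleleCatalog, MhcGenotypeMatrix
from mhcds.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at default settings, shared across tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture()
def tiny_catalog():
    """Three 9-bp alleles (no internal stops) for hand-checkable statistics."""
    return AlleleCatalog(
        {
            "a1": "TTTGGGGGG",
            "a2": "TTCGGGGGG",
            "a3": "TTTGGGGGA",
        },
        reference_length=9,
    )


@pytest.fixture()
def small_genotypes():
    """Two populations, four individuals, three alleles, known sharing."""
    return MhcGenotypeMatrix(
        individuals=["i1", "i2", "i3", "i4"],
        alleles=["a1", "a2", "a3"],
        presence=np.array(
            [
                [1, 1, 0],
                [1, 0, 0],
                [0, 1, 0],
                [0, 0, 1],
            ]
        ),
        population_of={"i1": "A", "i2": "A", "i3": "B", "i4": "B"},
    )


def random_distance_matrix(rng, n=12, dim=3):
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(rng.normal(0, 1, (n, dim))))
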