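import numpy as np
import pytest

from landcnn.landscape import Deme, DemeSet
from landcnn.raster import RasterGrid
from landcnn.resistance import MigrationEpoch, MigrationSchedule
from landcnn.simulate import GenotypeMatrix, ParameterDraw, StudyDesign, simulate_genotypes


@pytest.fixture
def uniform_raster():
    return RasterGrid(values=np.ones((10, 10)))


def make_two_deme_schedule(m: float, split_gen: float = 21_000.0) -> MigrationSchedule:
    mat = np.array([[0.0, m], [m, 0.0]])
    return MigrationSchedule(
        epochs=[MigrationEpoch(0.0, split_gen, mat)],
        dispersal=m,
        deme_ids=[1, 2],
    )


def make_two_deme_set(n_individuals: int = 5) -> DemeSet:
    return DemeSet(
        demes=[
            Deme(1, 1.5, 1.5, True, n_individuals),
            Deme(2, 8.5, 8.5, True, n_individuals),
        ]
    )


def simulate_two_demes(
    m: float,
    seed: int,
    n_snps: int = 50,
    n_individuals: int = 5,
    deme_size: float = 30.0,
    ancestral_ne: float = 30_000.0,
) -> GenotypeMatrix:
    """Small two-deme island simulation used across tests."""
    design = StudyDesign(n_demes=2, n_snps=n_snps)
    demes = make_two_deme_set(n_individuals)
    draw = ParameterDraw(
        ancestral_ne=ancestral_ne,
        deme_sizes=np.array([deme_size, deme_size]),
        effect_weights={},
        dispersal=m,
        seed=seed,
    )
    return simulate_genotypes(design, demes, draw, make_two_deme_schedule(m))


@pytest.fixture
def toy_genotypes():
    """4 sequences (2 individuals, 2 demes) x 3 SNPs with minor counts [1,3,2]."""
    g = np.array(
        [
            [1, 1, 0],
            [0, 1, 1],
            [0, 1, 1],
            [0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return GenotypeMatrix(
        genotypes=g,
        deme_ids=np.array([1, 1, 2, 2]),
        individual_ids=np.array([1, 1, 2, 2]),
        label=None,
    )
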