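import numpy as np
import pandas as pd
import pytest

from divscape import synth
from divscape.popgen import GenotypeTable
from divscape.raster import GridRaster


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world: 10x10 degrees at 30', 2 refugia, 2 alt climates."""
    return synth.generate_world(
        seed=11, n_vars=4, extent=(-75.0, -65.0, -5.0, 5.0),
        resolution_arcmin=30.0, n_refugia=2, refugium_radius_deg=1.2, n_alt=2,
    )


@pytest.fixture(scope="session")
def small_points(small_world):
    return synth.generate_presences(small_world, n_wild=40, n_cult=80, niche_shift=1.0)


@pytest.fixture(scope="session")
def small_genotypes(small_world, small_points):
    return synth.generate_genotypes(
        small_points, n_loci=9, alleles_per_locus=(4, 12),
        private_allele_rate=0.8, ibd_scale=3.0,
        refugia=small_world.refugia, seed=11,
    )


@pytest.fixture
def toy_table():
    """Three individuals, two loci, one missing pair; coordinates on a line."""
    calls = np.array(
        [
            [[3, 3], [1, 2]],
            [[3, 5], [1, 1]],
            [[5, 5], [0, 0]],
        ]
    )
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    return GenotypeTable(["a", "b", "c"], ["L1", "L2"], calls, coords)


@pytest.fixture
def unit_grid():
    """A 20x20-degree grid at 10 arc-minutes (120x120 cells)."""
    return GridRaster((-80.0, -60.0, -10.0, 10.0), 10.0)
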