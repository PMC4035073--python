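import numpy as np
import pytest

from introscan import (
    GenotypeMatrix,
    Group,
    MarkerMap,
    PopulationPanel,
    SimulationConfig,
    generate_fixture,
)

# call-string shorthand: R hom-ref, A hom-alt, H het, N missing
CODE = {"R": 0, "H": 1, "A": 2, "N": -1}


def geno_from_rows(
    rows,
    chromosomes=None,
    positions=None,
    marker_ids=None,
    cultivar_ids=None,
    alleles=None,
):
    """Build a GenotypeMatrix from per-cultivar call strings like "RAHN"."""
    n, m = len(rows), len(rows[0])
    chromosomes = chromosomes or ["chr1"] * m
    positions = positions if positions is not None else list(range(100, 100 + 100 * m, 100))
    marker_ids = marker_ids or [f"m{j}" for j in range(m)]
    cultivar_ids = cultivar_ids or [f"c{i}" for i in range(n)]
    alleles = alleles or [("A", "G")] * m
    calls = np.array([[CODE[ch] for ch in row] for row in rows], dtype=np.int8)
    return GenotypeMatrix(
        markers=MarkerMap.from_arrays(marker_ids, chromosomes, positions),
        cultivar_ids=cultivar_ids,
        calls=calls,
        alleles=np.array(alleles),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study bundle shared across tests (seed 0)."""
    return generate_fixture(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def hy_cultivars(default_bundle):
    return default_bundle.panel.members(Group.HY)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
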