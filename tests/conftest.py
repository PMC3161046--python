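import numpy as np
import pytest

from somatlas.io_formats import ExpressionMatrix, Scale
from somatlas.preprocess import center_profiles
from somatlas.som_core import (
    Assignment,
    SOMGrid,
    TrainedSOM,
    assign_genes,
    train_som,
)
from somatlas.synthetic_fixtures import default_fixture, generate_planted_modules

FIXTURE_SEED = 42


@pytest.fixture(scope="session")
def fixture_data():
    """Default planted-module fixture: 2000 genes x 24 samples, 4 modules."""
    return default_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def centered_fixture(fixture_data):
    matrix, truth, annotation = fixture_data
    return center_profiles(matrix), truth, annotation


@pytest.fixture(scope="session")
def trained_som(centered_fixture):
    centered, _, _ = centered_fixture
    return train_som(centered, SOMGrid(20, 20), seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small, fast fixture for pipeline smoke tests."""
    return generate_planted_modules(
        n_genes=300, n_samples=12, n_modules=3, genes_per_module=40,
        samples_per_module=4, delta=1.0, sigma=0.2, seed=7,
    )


def build_som(codebook: np.ndarray, x: int, y: int,
              sample_ids=None) -> TrainedSOM:
    """TrainedSOM where each node's minicluster holds exactly the node's own
    profile as a single 'gene' — handy for portrait/map unit tests."""
    codebook = np.asarray(codebook, dtype=float)
    grid = SOMGrid(x, y)
    assert codebook.shape[0] == grid.K
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(codebook.shape[1])]
    assignment = assign_genes(codebook, codebook,
                              gene_ids=[f"g{k}" for k in range(grid.K)])
    return TrainedSOM(grid, codebook, assignment, list(sample_ids))


def make_assignment(populations, gene_prefix="g") -> Assignment:
    """Assignment with prescribed per-node populations."""
    populations = np.asarray(populations, dtype=int)
    bmu = np.repeat(np.arange(len(populations)), populations)
    gene_ids = [f"{gene_prefix}{i}" for i in range(bmu.size)]
    members = [np.flatnonzero(bmu == k) for k in range(len(populations))]
    return Assignment(bmu, populations, members, gene_ids)


def grid_components(nodes, x: int, y: int, connectivity: int = 8) -> int:
    """Independent BFS connected-component count on the lattice."""
    nodes = set(int(k) for k in nodes)
    if connectivity == 8:
        steps = [(dc, dr) for dc in (-1, 0, 1) for dr in (-1, 0, 1)
                 if (dc, dr) != (0, 0)]
    else:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    seen: set[int] = set()
    components = 0
    for start in nodes:
        if start in seen:
            continue
        components += 1
        queue = [start]
        seen.add(start)
        while queue:
            k = queue.pop()
            col, row = k % x, k // x
            for dc, dr in steps:
                nc, nr = col + dc, row + dr
                if 0 <= nc < x and 0 <= nr < y:
                    nk = nr * x + nc
                    if nk in nodes and nk not in seen:
                        seen.add(nk)
                        queue.append(nk)
    return components


def random_matrix(n, m, seed=0, scale=Scale.LOG10) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        [f"g{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        rng.normal(2.0, 1.0, size=(n, m)),
        scale,
    )
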