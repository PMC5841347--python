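import numpy as np
import pytest

from traitgrid.assemblage import build_assemblages, filter_cells
from traitgrid.spatial import build_weights
from traitgrid.synthetic import fixture_config, generate_world
from traitgrid.traits import load_trait_table


@pytest.fixture(scope="session")
def fixture_world():
    """Small deterministic synthetic world (10x10 grid, 150 species)."""
    cfg = fixture_config(seed=0)
    world = generate_world(cfg)
    world["traits"] = load_trait_table(world["species"])
    return world


@pytest.fixture(scope="session")
def fixture_cells(fixture_world):
    cfg = fixture_world["config"]
    cells = build_assemblages(fixture_world["occurrences"],
                              fixture_world["traits"], cfg.grid)
    return filter_cells(cells)


@pytest.fixture(scope="session")
def lattice_20x20():
    """Row-standardised rook weights on a 20x20 lattice of 100 km cells."""
    xs, ys = np.meshgrid(np.arange(20), np.arange(20))
    centroids = np.column_stack([xs.ravel(), ys.ravel()]) * 100_000.0
    return centroids, build_weights(centroids, 150_000.0, "row_standardised")


@pytest.fixture(scope="session")
def lattice_10x10():
    xs, ys = np.meshgrid(np.arange(10), np.arange(10))
    centroids = np.column_stack([xs.ravel(), ys.ravel()]) * 100_000.0
    return centroids, build_weights(centroids, 150_000.0, "row_standardised")
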