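import numpy as np
import pandas as pd
import pytest

from sympatria.occurrence_io import OccurrenceTable, TraitTable
from sympatria.trees import Phylogeny


@pytest.fixture
def cherry():
    """Two tips, unit branches."""
    return Phylogeny.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    """Cherry (A,B) at depth 1 plus outgroup C — hand-solvable GLS geometry."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    """Balanced 4-tip tree, all unit branches."""
    return Phylogeny.from_newick("(((A:1,B:1):1,(C:1,D:1):1):0);")


def make_occurrences(clouds: dict) -> OccurrenceTable:
    """Build an occurrence table from {species: [(lon, lat), ...]}."""
    rows = [(sp, x, y) for sp, pts in clouds.items() for x, y in pts]
    return OccurrenceTable(pd.DataFrame(rows, columns=["species", "longitude", "latitude"]))


def random_clouds(rng: np.random.Generator, n_species: int, n_points: int,
                  box=(0.0, 0.0, 1.0, 1.0)) -> OccurrenceTable:
    """Random point clouds, one per species, uniform in a lon/lat box."""
    lo_x, lo_y, hi_x, hi_y = box
    clouds = {
        f"s{i}": list(zip(rng.uniform(lo_x, hi_x, n_points), rng.uniform(lo_y, hi_y, n_points)))
        for i in range(n_species)
    }
    return make_occurrences(clouds)


@pytest.fixture
def uniform_traits():
    """Nine species in three well-separated size clusters."""
    vals = {"a1": 40.0, "a2": 41.0, "a3": 42.0,
            "b1": 70.0, "b2": 71.0, "b3": 72.0,
            "c1": 120.0, "c2": 121.0, "c3": 122.0}
    return TraitTable(vals)
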