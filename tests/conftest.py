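import numpy as np
import pandas as pd
import pytest

from parafauna import GridSpec, PresenceAbsenceMatrix, WorldConfig, simulate


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(0, 10, 0, 10, 1.0)


@pytest.fixture(scope="session")
def toy_pam(small_grid) -> PresenceAbsenceMatrix:
    """Three hosts with hand-placed ranges: A in cells {1, 2}, B in {1}, C in {1, 2}."""
    values = np.zeros((3, small_grid.n_cells), dtype=int)
    values[0, [1, 2]] = 1
    values[1, 1] = 1
    values[2, [1, 2]] = 1
    return PresenceAbsenceMatrix(["A", "B", "C"], small_grid, values)


@pytest.fixture(scope="session")
def random_pam(small_grid) -> PresenceAbsenceMatrix:
    rng = np.random.default_rng(17)
    values = (rng.random((50, small_grid.n_cells)) < 0.15).astype(int)
    values[values.sum(axis=1) == 0, 0] = 1  # every host occupies >= 1 cell
    return PresenceAbsenceMatrix([f"h{i:02d}" for i in range(50)], small_grid, values)


@pytest.fixture(scope="session")
def small_tree():
    return simulate.generate_phylogeny(12, seed=42)


@pytest.fixture(scope="session")
def sharing_world() -> simulate.SyntheticWorld:
    """A sharing-mode realm at reduced size for unit tests."""
    return simulate.generate_world(WorldConfig(
        n_hosts=60, n_parasites=25, seed=9, mode="sharing", sharing_distance="trait"))


@pytest.fixture(scope="session")
def richness_world() -> simulate.SyntheticWorld:
    return simulate.generate_world(WorldConfig(
        n_hosts=200, n_parasites=200, seed=5, mode="richness",
        grid=GridSpec(0, 20, 10, 30, 1.0)))
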