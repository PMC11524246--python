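"""Shared fixtures: small grids, weights, and a tiny synthetic panel."""

import numpy as np
import pandas as pd
import pytest

from invascape.units import UnitSystem, grid_partition
from invascape.weights import SpatialWeights, build_contiguity, row_standardize


@pytest.fixture(scope="session")
def grid5() -> UnitSystem:
    return grid_partition((0.0, 0.0, 5000.0, 5000.0), 5, 5, "G5")


@pytest.fixture(scope="session")
def queen5(grid5) -> SpatialWeights:
    return row_standardize(build_contiguity(grid5, "queen"))


@pytest.fixture(scope="session")
def grid10() -> UnitSystem:
    return grid_partition((0.0, 0.0, 10000.0, 10000.0), 10, 10, "G10")


@pytest.fixture(scope="session")
def queen10(grid10) -> SpatialWeights:
    return row_standardize(build_contiguity(grid10, "queen"))


@pytest.fixture()
def chain3() -> SpatialWeights:
    """Three units in a line, rook adjacency, row-standardized."""
    return SpatialWeights(
        ids=["a", "b", "c"],
        neighbors=[np.array([1]), np.array([0, 2]), np.array([1])],
        style="row",
    )


@pytest.fixture(scope="session")
def tiny_panel():
    """400-subplot synthetic panel over a 2x2 unit system with known truth."""
    from invascape.synthetic import (
        generate_subplot_network,
        simulate_occurrences,
    )

    units = grid_partition((0.0, 0.0, 49000.0, 49000.0), 2, 2, "Q")
    skeleton = generate_subplot_network([units], 4900.0, 4, 0.0, seed=7)
    severity = pd.Series([2.0, 4.0, 6.0, 8.0], index=units.unit_ids)
    panel = simulate_occurrences(
        skeleton, units, severity, cycle_multipliers=(1.0, 1.2, 1.4), seed=11
    )
    return units, severity, panel
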