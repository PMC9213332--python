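"""Shared fixtures: biological parameter sets and cached coefficient fields.

Coefficient construction integrates the survival kernel over a long
time-since-damage axis for every trait node, so the expensive default-grid
fields are built once per session; most unit tests use a coarser grid.
"""

import pytest

from dnadapt import (BioParams, TraitGrid, effective_coefficients)


@pytest.fixture(scope="session")
def bio_x() -> BioParams:
    """Timing-trait parameters (p-bar = 3)."""
    return BioParams.timing(p_bar=3.0)


@pytest.fixture(scope="session")
def bio_p() -> BioParams:
    """Heterogeneity-trait parameters (x-bar = 4)."""
    return BioParams.heterogeneity(x_bar=4.0)


@pytest.fixture(scope="session")
def coarse_grid() -> TraitGrid:
    return TraitGrid(x_max=12.0, M=241)


@pytest.fixture(scope="session")
def fine_grid() -> TraitGrid:
    return TraitGrid.default()


@pytest.fixture(scope="session")
def field_x_coarse(coarse_grid, bio_x):
    return effective_coefficients(coarse_grid, bio_x)


@pytest.fixture(scope="session")
def field_x_fine(fine_grid, bio_x):
    return effective_coefficients(fine_grid, bio_x)


@pytest.fixture(scope="session")
def field_p_fine(fine_grid, bio_p):
    return effective_coefficients(fine_grid, bio_p)
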