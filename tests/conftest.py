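"""Shared fixtures: small phantoms and field sets built programmatically."""

import numpy as np
import pytest

from mhfocus import (
    GridSpec,
    PhantomGrid,
    generate_phantom,
    make_layout,
    simulate_unit_fields,
)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 3 mm grid covering the same physical extent class as default."""
    return GridSpec(n_rows=24, n_cols=32, pixel_mm=3.0)


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return generate_phantom(seed=7, grid=small_grid)


@pytest.fixture(scope="session")
def small_linear_fieldset(small_phantom):
    layout = make_layout("linear", small_phantom.grid, small_phantom)
    return simulate_unit_fields(small_phantom, layout)


@pytest.fixture(scope="session")
def small_circular_fieldset(small_phantom):
    layout = make_layout("circular", small_phantom.grid, small_phantom)
    return simulate_unit_fields(small_phantom, layout)


@pytest.fixture(scope="session")
def default_phantom():
    """Paper-scale 71 x 91 grid at 1 mm."""
    return generate_phantom(seed=1)


def homogeneous_phantom(grid, eps_r=30.0, sigma=1.2):
    """All-breast constant-dielectric phantom (for closed-form field checks)."""
    return PhantomGrid(
        grid=grid,
        eps_r=np.full(grid.shape, eps_r),
        sigma=np.full(grid.shape, sigma),
        breast_mask=np.ones(grid.shape, dtype=bool),
    )


def lossless_phantom(grid):
    """Vacuum grid: no breast, sigma=0, eps_r=1 everywhere."""
    return PhantomGrid(
        grid=grid,
        eps_r=np.ones(grid.shape),
        sigma=np.zeros(grid.shape),
        breast_mask=np.zeros(grid.shape, dtype=bool),
    )


@pytest.fixture(scope="session")
def tiny_grid():
    """Smallest legal grid for fast CNN unit tests."""
    return GridSpec(n_rows=16, n_cols=16, pixel_mm=1.0)


@pytest.fixture(scope="session")
def tiny_linear_fieldset(tiny_grid):
    phantom = generate_phantom(seed=3, grid=tiny_grid, heterogeneity=2.0)
    layout = make_layout("linear", tiny_grid, phantom)
    return phantom, simulate_unit_fields(phantom, layout)
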