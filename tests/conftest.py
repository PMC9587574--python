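import numpy as np
import pytest

from segqa import (
    GridSpec,
    PredictionSetConfig,
    generate_experiment_suite,
    make_head_phantom,
    simulate_model_predictions,
)


@pytest.fixture(scope="session")
def unit_grid():
    """Small isotropic 1 mm grid for constructed fixtures."""
    return GridSpec((24, 24, 24))


@pytest.fixture(scope="session")
def aniso_grid():
    """Anisotropic grid emulating 3 mm CT slices."""
    return GridSpec((20, 20, 12), (1.0, 1.0, 3.0))


def digitized_ball(radius_mm: float, spacing=(1.0, 1.0, 1.0), pad: int = 4):
    """Rasterize a ball centered on a voxel center; returns (mask, grid)."""
    spacing = np.asarray(spacing, float)
    half = np.ceil(radius_mm / spacing).astype(int) + pad
    shape = tuple(2 * half + 1)
    grid = GridSpec(shape, tuple(spacing))
    center = (np.asarray(shape) - 1) / 2 * spacing
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        (x * spacing[0] - center[0]) ** 2
        + (y * spacing[1] - center[1]) ** 2
        + (z * spacing[2] - center[2]) ** 2
    )
    return d2 <= radius_mm**2, grid


@pytest.fixture(scope="session")
def suite_grid():
    return GridSpec((128, 128, 128), (1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def experiment_suite(suite_grid):
    """The full 61-scenario controlled-experiment suite (built once)."""
    base = make_head_phantom(suite_grid, seed=1)
    return generate_experiment_suite(suite_grid, base)


@pytest.fixture(scope="session")
def prediction_study():
    """20 phantom cases x 5 models with injected outliers, plus the logs.

    Returns (grid, list of (truth, predictions, log)) — the parameter-recovery
    ground truth for the component-inventory tests.
    """
    grid = GridSpec((64, 64, 64), (2.0, 2.0, 2.0))
    cases = []
    for case in range(20):
        truth = make_head_phantom(grid, seed=100 + case)
        preds, log = simulate_model_predictions(
            truth, PredictionSetConfig(seed=500 + case)
        )
        cases.append((truth, preds, log))
    return grid, cases
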