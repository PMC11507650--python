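import numpy as np
import pytest

from crabspec import SyntheticConfig, WavenumberGrid, generate_dataset


@pytest.fixture(scope="session")
def small_grid() -> WavenumberGrid:
    """Coarse 311-point version of the acquisition grid (step 20 cm^-1)."""
    return WavenumberGrid(10_000.0, 3_800.0, 20.0)


@pytest.fixture(scope="session")
def band_indices(small_grid) -> np.ndarray:
    """Grid positions inside the two planted discriminative bands."""
    return np.concatenate(
        [small_grid.band_indices(10_000, 9_500), small_grid.band_indices(9_000, 8_500)]
    )


@pytest.fixture(scope="session")
def study_dataset(small_grid):
    """Default study conditions: 130 samples per origin, calibrated signal."""
    return generate_dataset(SyntheticConfig(grid=small_grid, seed=3))


@pytest.fixture(scope="session")
def tiny_dataset(small_grid):
    """Small, strongly separated dataset for fast model tests."""
    cfg = SyntheticConfig(
        grid=small_grid,
        n_per_class=20,
        seed=11,
        class_band_effects={"WL": (0.3, 0.0), "TL": (0.0, 0.3), "HL": (0.3, 0.3)},
        noise_sd=0.02,
    )
    return generate_dataset(cfg)
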