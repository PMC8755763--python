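import numpy as np
import pytest

from chondrohsi import (
    AbsorbanceCube,
    GeneratorConfig,
    RawCube,
    ReferenceSet,
    WavelengthGrid,
)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_absorbance_cube(grid, rng) -> AbsorbanceCube:
    """8x8 cube of random absorbance values in a physiological range."""
    return AbsorbanceCube(rng.uniform(0.1, 2.0, size=(8, 8, grid.n_bands)), grid)


@pytest.fixture()
def flat_references(grid) -> ReferenceSet:
    white = np.full((1, 1, grid.n_bands), 1000.0)
    dark = np.full((1, 1, grid.n_bands), 100.0)
    return ReferenceSet(white=white, dark=dark)


@pytest.fixture()
def noisefree_config() -> GeneratorConfig:
    """Small noise-free cohort for fast end-to-end runs."""
    return GeneratorConfig(
        n_patients=4, cube_shape=(32, 32), roi_radius=4,
        noise_cv=0.0, dark_noise_sd=0.0, seed=7,
    )


def make_raw_from_reflectance(reflectance: np.ndarray, grid, refs) -> RawCube:
    """Invert the calibration: I0 = Idark + IR * (Iwhite - Idark)."""
    i0 = refs.dark + reflectance * (refs.white - refs.dark)
    return RawCube(i0, grid)
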