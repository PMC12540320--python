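import numpy as np
import pytest

from seedspec import (
    NoiseModel,
    TrayLayout,
    WavelengthGrid,
    gen_spectrum_set,
    gen_tray_cube,
    make_varieties,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def small_set():
    """5 easy classes x 24 seeds — quick, cleanly separable."""
    varieties = make_varieties(5, 11, class_scale=1.0)
    return gen_spectrum_set(varieties, 24, NoiseModel(seed=12))


@pytest.fixture(scope="session")
def tray():
    """One noiseless 5x6 tray scan with distinct classes per cell."""
    varieties = make_varieties(30, 3)
    raw, white, dark, truth = gen_tray_cube(
        varieties, TrayLayout(), NoiseModel.silent(4)
    )
    return varieties, raw, white, dark, truth


@pytest.fixture
def rng():
    return np.random.default_rng(99)
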