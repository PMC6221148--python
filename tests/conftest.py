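import numpy as np
import pytest

import mimicvis as mv


@pytest.fixture(scope="session")
def grid():
    return mv.DEFAULT_GRID


@pytest.fixture(scope="session")
def d65(grid):
    return mv.standard_illuminant("D65", grid)


@pytest.fixture(scope="session")
def flat_illum(grid):
    return mv.standard_illuminant("flat", grid)


@pytest.fixture(scope="session")
def bluetit():
    return mv.build_preset("bluetit-uvs")


@pytest.fixture(scope="session")
def erato_female_green():
    return mv.build_preset("erato-female-green")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_smooth_reflectance(grid, rng, floor=0.05):
    """A random smooth, strictly positive reflectance for property tests."""
    lam = grid.wavelengths
    vals = np.full(lam.shape, rng.uniform(floor, 0.3))
    for _ in range(3):
        c = rng.uniform(320, 680)
        w = rng.uniform(50, 150)
        vals = vals + rng.uniform(0, 0.5) * np.exp(-(((lam - c) / w) ** 2))
    return mv.Spectrum(grid=grid, values=np.clip(vals, floor, 1.4),
                       kind="reflectance")
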