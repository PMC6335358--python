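import numpy as np
import pytest

from meanet import MEAGeometry, SpikeRaster, standard_mea


@pytest.fixture(scope="session")
def geom() -> MEAGeometry:
    return standard_mea()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_raster(spikes: dict[int, list[float]], duration: float,
                geometry=None) -> SpikeRaster:
    return SpikeRaster(
        {ch: np.asarray(t, dtype=float) for ch, t in spikes.items()},
        duration=duration,
        geometry=geometry,
    )
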