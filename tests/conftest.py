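import numpy as np
import pytest

from wetlandval import (
    ScenarioSpec,
    generate_price_field,
    make_panan_fixture,
)


@pytest.fixture(scope="session")
def panan_dir(tmp_path_factory):
    """On-disk Pan'an Lake fixture bundle (rasters, legend, coefficients)."""
    out = tmp_path_factory.mktemp("panan_fixture")
    make_panan_fixture(out, seed=7)
    return out


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced two-epoch price scenario for fast unit tests.

    3 km x 3 km at 30 m cells, 120 samples per epoch, kernel radius 600 m;
    the default planned-plot ring (450 m radius) sits inside the kernel.
    """
    spec = ScenarioSpec(
        width=3000.0, height=3000.0, cell_size=30.0,
        n_before=120, n_after=120,
        radius=600.0, focus_radius=800.0,
        seed=42,
    )
    return generate_price_field(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
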