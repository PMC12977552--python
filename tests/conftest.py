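import numpy as np
import pytest

from retquant import synthetic
from retquant.counting import CountingConfig


@pytest.fixture(scope="session")
def default_config() -> CountingConfig:
    return CountingConfig.from_geometry(0.5)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, gradient-free flat-mount tile with well-separated somas."""
    spec = synthetic.FlatMountSpec(
        width_px=384,
        height_px=384,
        retina_radius_um=70.0,  # keeps all somas well away from the borders
        n_cells=25,
        clump_fraction=0.0,
        noise_sd=0.0,
        gradient_amplitude=0.0,
        min_separation_um=16.0,
        seed=11,
    )
    return spec, *synthetic.generate_flatmount(spec)


@pytest.fixture(scope="session")
def default_tile():
    """One default-realism tile (noise, gradient, clumps)."""
    spec = synthetic.FlatMountSpec(seed=3)
    return spec, *synthetic.generate_flatmount(spec)
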