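import numpy as np
import pytest

from petstage.phantom import PhantomConfig, build_template


def desk_config(grid: int = 32, **overrides) -> PhantomConfig:
    """Phantom on a desk-scale grid covering the same 128 mm world box."""
    spacing = 128.0 / grid
    return PhantomConfig(grid_shape=(grid,) * 3, spacing=(spacing,) * 3, **overrides)


@pytest.fixture(scope="session")
def config32() -> PhantomConfig:
    return desk_config(32)


@pytest.fixture(scope="session")
def template32(config32):
    return build_template(config32)


@pytest.fixture(scope="session")
def atlas32(template32):
    return template32[1]
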