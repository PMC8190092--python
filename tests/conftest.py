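import numpy as np
import pytest

from thylaquant.synthetic_scenes import (
    OpticsNoiseParams,
    ProteinDistributionParams,
    make_scene,
)


@pytest.fixture
def quiet_optics() -> OpticsNoiseParams:
    """Noise-free fluorescence optics (blur only)."""
    return OpticsNoiseParams(background=0.0, poisson_gain=0.0, read_sigma=0.0)


@pytest.fixture
def empty_distribution() -> ProteinDistributionParams:
    return ProteinDistributionParams(n_points=0)


@pytest.fixture
def gl_scene_quiet(quiet_optics, empty_distribution):
    """One noise-free growth-light cell without protein points."""
    return make_scene(
        "GL", distribution=empty_distribution, optics=quiet_optics, seed=42
    )


@pytest.fixture(autouse=True)
def _silence_degenerate_warnings():
    """Tests assert on warnings explicitly where they matter."""
    yield
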