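import numpy as np
import pytest

from ramancs.io import WavenumberAxis
from ramancs.synthetic import (Endmember, SceneSpec, default_axis,
                               make_cell_scene, make_mixture_series,
                               make_tissue_scene, tissue_test_spec)


@pytest.fixture
def axis():
    return default_axis()


@pytest.fixture
def small_axis():
    """Short axis for cheap per-spectrum tests."""
    return WavenumberAxis(np.linspace(600.0, 1800.0, 64))


@pytest.fixture
def noiseless_mixture():
    """Exact two-component mixture series: rank-2, no baseline, no noise."""
    return make_mixture_series(noise_sd=0.0, baseline_amplitude=0.0, seed=0)


@pytest.fixture
def noisy_mixture():
    return make_mixture_series(seed=0)


@pytest.fixture
def cell_scene():
    cube, truth = make_cell_scene()
    return cube, truth


@pytest.fixture
def clean_cell_scene():
    """Cell scene without noise or baseline: detection is exact."""
    spec = SceneSpec(grid=(32, 36), noise_sd=0.0, baseline_amplitude=0.0, seed=3)
    return make_cell_scene(spec)


@pytest.fixture
def tissue_scene():
    spec = tissue_test_spec(seed=1)
    return make_tissue_scene(spec)
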