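import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tmstarget import default_spec, isotropic_grid, make_subject


@pytest.fixture(scope="session")
def unit_grid():
    """8^3 grid of 1 mm voxels at the origin."""
    return isotropic_grid((8, 8, 8), 1.0)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down phantom: same structure as the default, faster to generate."""
    return default_spec(
        shape=(28, 28, 28), voxel_mm=2.0, head_radius_mm=24.0,
        shell_gap_mm=5.0, shell_thickness_mm=8.0, fold_frequency=3,
        fold_amplitude_mm=2.5, network_radius_mm=14.0, search_radius_mm=16.0,
        T=150,
    )


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return make_subject(small_spec, subject_seed=11, session_seeds=[21, 22])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
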