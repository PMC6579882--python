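import numpy as np
import pytest

import somatoseg as ss
from somatoseg.core import ParadigmSpec
from somatoseg.synth import make_roi_masks


@pytest.fixture(scope="session")
def presets():
    return ss.default_protocol_presets()


@pytest.fixture(scope="session")
def cells():
    return ss.factorial_cells()


@pytest.fixture(scope="session")
def paradigm():
    return ParadigmSpec()


@pytest.fixture(scope="session")
def rois_default():
    return make_roi_masks()


@pytest.fixture(scope="session")
def rois_small():
    return make_roi_masks(grid_shape=(28, 36, 28), box_shape=(6, 6, 6))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pipeline_result(tmp_path_factory):
    """One shared reduced-size end-to-end run (3 subjects, small grid)."""
    cfg = ss.RunConfig(n_subjects=3, grid_shape=(28, 36, 28), box_shape=(6, 6, 6),
                       seed=7)
    out = tmp_path_factory.mktemp("pipe")
    return ss.run_pipeline(cfg, out_dir=out), out
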