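import numpy as np
import pytest

from prolifatlas.phantom import PhantomSpec, generate_specimen
from prolifatlas.volio import CellMap, LabeledVolume


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 64³ at 8 µm, same world extent as the default grid."""
    return PhantomSpec(grid_shape=(64, 64, 64), spacing_iso=8.0, seed=7)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, identity-pose phantom for exact geometric assertions."""
    return PhantomSpec(
        grid_shape=(64, 64, 64), spacing_iso=8.0, boundary_jitter=0.0,
        landmark_jitter=0.0, specimen_scale_sd=0.0, specimen_rot_deg=0.0,
        specimen_shift_um=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def clean_specimen(clean_spec):
    return generate_specimen(clean_spec, "E10.5", 0)


@pytest.fixture()
def ball_volume():
    """Solid ball of radius 60 µm in a 48³ grid at 4 µm."""
    shape = (48, 48, 48)
    sp = (4.0, 4.0, 4.0)
    idx = np.indices(shape).transpose(1, 2, 3, 0) * np.array(sp)
    c = (np.array(shape) - 1) * np.array(sp) / 2
    mask = np.linalg.norm(idx - c, axis=-1) < 60.0
    return LabeledVolume(mask.astype(np.int16), sp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_cellmap(mask, spacing=(4.0, 4.0, 4.0), channel="nuclei"):
    return CellMap(np.asarray(mask, dtype=bool), spacing, channel=channel)
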